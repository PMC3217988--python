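"""Hairpin discovery: EST mapping, context windows, duplex criteria, stars."""

import numpy as np
import pytest

from srnamir.discover import (DuplexCriteria, RejectedCandidate, detect_star,
                              discover_mirnas, evaluate_candidate,
                              extract_context, infer_star, map_to_ests,
                              revcomp, summarize_novel, trim_precursor)
from srnamir.fold import structure_from_pairs
from srnamir.preprocess import SmallRNATag
from srnamir.report import load_novel_reference_table
from srnamir.synthetic import SimulationConfig, build_hairpin_insert, \
    make_est_collection

TAG = "ACGGATGCATTGAGGATCCAT"  # 21 nt


class TestMapToEsts:
    def test_planted_occurrence_found(self):
        ests = {"e1": "T" * 100 + TAG + "G" * 100}
        assert map_to_ests(TAG, ests) == [("e1", 100, "+")]

    def test_absent_tag_yields_empty(self):
        assert map_to_ests(TAG, {"e1": "T" * 200}) == []

    def test_double_occurrence_matches_brute_force(self):
        est = "G" * 30 + TAG + "C" * 40 + TAG + "A" * 30
        hits = map_to_ests(TAG, {"e1": est})
        brute = [("e1", i, "+") for i in range(len(est) - len(TAG) + 1)
                 if est[i:i + len(TAG)] == TAG]
        assert hits == brute == [("e1", 30, "+"), ("e1", 91, "+")]

    def test_minus_strand_hit(self):
        ests = {"e1": "G" * 50 + revcomp(TAG) + "T" * 50}
        assert map_to_ests(TAG, ests) == [("e1", 50, "-")]


class TestExtractContext:
    def test_interior_hit_window_length(self):
        est = "A" * 1000
        window, ts = extract_context(est, ("e", 200, "+"), 21)
        assert len(window) == 150 + 21 + 150
        assert ts == 150

    def test_left_truncated_window(self):
        est = "C" * 500
        window, ts = extract_context(est, ("e", 10, "+"), 21)
        assert len(window) == 10 + 21 + 150
        assert ts == 10

    def test_minus_strand_is_reverse_complement_of_plus(self):
        rng = np.random.default_rng(0)
        est = "".join(rng.choice(np.array(list("ACGT")), 600))
        plus, ts_p = extract_context(est, ("e", 250, "+"), 21)
        minus, ts_m = extract_context(est, ("e", 250, "-"), 21)
        assert minus == revcomp(plus)
        assert ts_m == len(plus) - ts_p - 21


def hairpin_structure(arm, loop, unpaired_5p=()):
    """Perfect hairpin structure with selected 5'-arm positions unpaired."""
    pairs = []
    n = 2 * arm + loop
    for i in range(arm):
        if i not in unpaired_5p:
            pairs.append((i, n - 1 - i))
    return structure_from_pairs(n, pairs), n


class TestEvaluateCandidate:
    CRIT = DuplexCriteria()

    def test_compliant_hairpin_accepted(self):
        structure, n = hairpin_structure(40, 12)
        window = "G" * n
        cand = evaluate_candidate(window, 5, 21, structure, -30.0, self.CRIT)
        assert cand.arm == "5p"
        assert cand.mature_offset == 5

    def test_mature_spanning_loop_rejected(self):
        structure, n = hairpin_structure(40, 12)
        with pytest.raises(RejectedCandidate) as exc:
            evaluate_candidate("G" * n, 30, 21, structure, -30.0, self.CRIT)
        assert exc.value.reason == "loop_overlap"

    def test_five_unpaired_mature_bases_rejected(self):
        structure, n = hairpin_structure(40, 12,
                                         unpaired_5p=(7, 9, 11, 13, 15))
        with pytest.raises(RejectedCandidate) as exc:
            evaluate_candidate("G" * n, 5, 21, structure, -30.0, self.CRIT)
        assert exc.value.reason == "excess_mismatch"

    def test_four_unpaired_mature_bases_accepted(self):
        structure, n = hairpin_structure(40, 12, unpaired_5p=(7, 9, 11, 13))
        cand = evaluate_candidate("G" * n, 5, 21, structure, -30.0, self.CRIT)
        assert cand is not None

    def test_asymmetric_bulge_rejected(self):
        # pair mature around a 4-nt bulge on the star side
        pairs = [(i, 119 - i) for i in range(10)]
        pairs += [(i, 115 - i) for i in range(10, 40)]  # partners jump by 4
        structure = structure_from_pairs(120, pairs)
        with pytest.raises(RejectedCandidate) as exc:
            evaluate_candidate("G" * 120, 5, 21, structure, -30.0, self.CRIT)
        assert exc.value.reason == "bulge"

    def test_nonnegative_energy_rejected(self):
        structure, n = hairpin_structure(40, 12)
        with pytest.raises(RejectedCandidate) as exc:
            evaluate_candidate("G" * n, 5, 21, structure, 0.0, self.CRIT)
        assert exc.value.reason == "nonnegative_mfe"

    def test_mature_length_bounds(self):
        structure, n = hairpin_structure(40, 12)
        with pytest.raises(RejectedCandidate) as exc:
            evaluate_candidate("G" * n, 5, 19, structure, -30.0, self.CRIT)
        assert exc.value.reason == "mature_length"

    def test_tag_outside_window_is_logic_error(self):
        structure, n = hairpin_structure(40, 12)
        with pytest.raises(ValueError):
            evaluate_candidate("G" * n, n - 5, 21, structure, -30.0,
                               self.CRIT)


class TestStarInference:
    def test_register_on_perfect_stem(self):
        # seamless stem: star span must sit 2 nt inside/outside per overhang
        arm, loop = 40, 12
        structure, n = hairpin_structure(arm, loop)
        ts, L = 5, 21
        span = infer_star("G" * n, structure, ts, L)
        te = ts + L
        assert span == (n - 1 - (te - 3), n - 1 - ts + 3)

    def test_star_sequence_matches_planted(self):
        rng = np.random.default_rng(3)
        mature = "".join(rng.choice(np.array(list("ACGT")), 22))
        insert, off, star = build_hairpin_insert(mature, rng,
                                                 target_length=120)
        from srnamir.fold import fold_mfe
        structure, mfe = fold_mfe(insert)
        cand = evaluate_candidate(insert, off, 22, structure, mfe,
                                  DuplexCriteria(), mature_count=10)
        cand = detect_star(cand, {star: 4})
        assert cand.star_seq == star.replace("T", "U")
        assert cand.star_count == 4
        assert cand.star_supported

    def test_unsupported_star_flagged(self):
        rng = np.random.default_rng(3)
        mature = "".join(rng.choice(np.array(list("ACGT")), 22))
        insert, off, star = build_hairpin_insert(mature, rng,
                                                 target_length=120)
        from srnamir.fold import fold_mfe
        structure, mfe = fold_mfe(insert)
        cand = evaluate_candidate(insert, off, 22, structure, mfe,
                                  DuplexCriteria(), mature_count=10)
        one_mismatch = "A" + star[1:] if star[0] != "A" else "C" + star[1:]
        cand = detect_star(cand, {one_mismatch: 9})
        assert cand.star_seq is not None
        assert cand.star_count == 0  # exact match only
        assert not cand.star_supported


class TestDiscoveryRecovery:
    def test_planted_hairpins_recovered(self):
        cfg = SimulationConfig(seed=21, n_hairpins=12, n_ests=20)
        ests, planted = make_est_collection(cfg)
        tags = []
        seen = set()
        for p in planted:
            for seq, count in ((p.mature_seq, 40), (p.star_seq, 4)):
                if seq not in seen:
                    tags.append(SmallRNATag(seq, count))
                    seen.add(seq)
        result = discover_mirnas(tags, ests)
        accepted = {c.mature_seq for c in result.candidates}
        recovered = sum(p.mature_seq.replace("T", "U") in accepted
                        for p in planted)
        assert recovered == len(planted)
        assert len(result.candidates) == len(planted)  # deduplicated
        assert all(c.star_supported for c in result.candidates)
        for cand in result.candidates:
            cand.validate()

    def test_background_tags_yield_no_candidates(self):
        rng = np.random.default_rng(8)
        ests = {f"e{i}": "".join(rng.choice(np.array(list("ACGT")), 500))
                for i in range(5)}
        tags = [SmallRNATag("".join(rng.choice(np.array(list("ACGT")), 21)),
                            1) for _ in range(200)]
        result = discover_mirnas(tags, ests)
        assert result.candidates == []


class TestSummarizeNovel:
    def test_reference_table_statistics(self):
        table = load_novel_reference_table()
        stats = summarize_novel(table)
        assert stats["n_rows"] == 29
        assert stats["n_families"] == 25
        assert stats["mean_mfe"] == -50.01
        assert stats["min_mfe"] == -87.2
        assert stats["max_mfe"] == -21.9
        assert stats["max_precursor_length"] == 343
        assert stats["band_fraction"] == pytest.approx(0.88)
        assert stats["n_high_read_families"] == 5
        assert stats["n_low_read_families"] == 9
        assert stats["max_count"] == 5716

    def test_empty_table_is_error(self):
        import pandas as pd
        with pytest.raises(ValueError):
            summarize_novel(pd.DataFrame(columns=["name", "count"]))
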