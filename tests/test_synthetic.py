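"""Generator contracts: determinism, disjointness, mixtures, ground truth."""

import math

import numpy as np
import pytest

from srnamir.discover import revcomp
from srnamir.fold import fold_mfe, pair_table
from srnamir.synthetic import (DefectSpec, SimulationConfig,
                               build_hairpin_insert, build_target_site,
                               make_est_collection, make_reference_sets,
                               plant_hairpin, plant_target_sites,
                               simulate_library, make_transcripts)


def cfg(**kw):
    return SimulationConfig(**{"seed": 1, "n_reads": 4000, "n_hairpins": 5,
                               "n_ests": 10, **kw})


class TestReferenceSets:
    def test_sizes_and_lengths(self):
        refs = make_reference_sets(cfg())
        assert len(refs["miRNA"]) == 30
        assert all(20 <= len(s) <= 24 for s in refs["miRNA"].values())
        assert all(18 <= len(s) <= 28 for s in refs["rRNA"].values())

    def test_classes_are_disjoint(self):
        refs = make_reference_sets(cfg())
        pools = [set(seqs.values()) for seqs in refs.values()]
        for i in range(len(pools)):
            for j in range(i + 1, len(pools)):
                assert not pools[i] & pools[j]

    def test_same_seed_is_byte_identical(self, tmp_path):
        from srnamir.synthetic import write_fasta
        a, b = tmp_path / "a.fa", tmp_path / "b.fa"
        write_fasta(make_reference_sets(cfg())["miRNA"], str(a))
        write_fasta(make_reference_sets(cfg())["miRNA"], str(b))
        assert a.read_bytes() == b.read_bytes()

    def test_zero_size_contaminant_class_is_error(self):
        c = cfg()
        c.class_sizes["rRNA"] = 0
        with pytest.raises(ValueError):
            make_reference_sets(c)


class TestConfigValidation:
    def test_length_weights_must_sum_to_one(self):
        c = cfg()
        c.length_weights = {21: 0.5, 24: 0.6}
        with pytest.raises(ValueError):
            c.validate()

    def test_proportions_bounded_by_one(self):
        c = cfg(known_mirna_fraction=0.9)
        c.contaminant_fractions = {"rRNA": 0.3}
        with pytest.raises(ValueError):
            c.validate()

    def test_default_config_is_valid(self):
        SimulationConfig().validate()


class TestPlantHairpin:
    def test_mature_at_recorded_offset_and_duplex_folds(self):
        rng = np.random.default_rng(5)
        est = "".join(rng.choice(np.array(list("ACGT")), 500))
        mature = "".join(rng.choice(np.array(list("ACGT")), 22))
        modified, offset, star = plant_hairpin(est, mature, rng)
        assert len(modified) == len(est)
        assert modified[offset:offset + 22] == mature
        assert star in modified
        # verify by folding with the pipeline's own engine: the mature must
        # pair against the star arm with at most 4 unpaired positions
        start = modified.find(star) - 200
        window = modified[max(0, offset - 60):offset + 250]
        ts = offset - max(0, offset - 60)
        structure, mfe = fold_mfe(window)
        partner = pair_table(structure)
        unpaired = sum(partner[i] is None for i in range(ts, ts + 22))
        assert mfe < 0
        assert unpaired <= 4

    def test_short_mature_is_precondition_error(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            plant_hairpin("A" * 400, "ACGTACGTACGTACGTACG", rng)  # 19 nt

    def test_short_est_rejected_with_message(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="too short"):
            plant_hairpin("A" * 60, "ACGTACGTACGTACGTACGTA", rng)

    def test_deterministic_given_seed(self):
        est = "ACGT" * 120
        mature = "ACGGATGCATTGAGGATCCAT"
        out1 = plant_hairpin(est, mature, np.random.default_rng(9))
        out2 = plant_hairpin(est, mature, np.random.default_rng(9))
        assert out1 == out2

    def test_insert_length_range(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            mature = "".join(rng.choice(np.array(list("ACGT")), 21))
            insert, off, star = build_hairpin_insert(mature, rng)
            assert 75 <= len(insert) <= 343


class TestSimulateLibrary:
    def test_class_mixture_within_binomial_error(self):
        c = cfg(n_reads=10_000, seed=3)
        refs = make_reference_sets(c)
        ests, planted = make_est_collection(c)
        reads, truth = simulate_library(c, refs, planted)
        counts = truth.class_counts()
        n = c.n_reads
        # adapter-only reads are drawn first; class draws cover the rest
        n_classed = n - counts.get("adapter", 0)
        p = c.known_mirna_fraction
        expect = n_classed * p
        sigma = math.sqrt(n_classed * p * (1 - p))
        assert abs(counts["miRNA"] - expect) <= 3 * sigma

    def test_ground_truth_closure(self, small_sim):
        c, refs, ests, planted, reads, truth = small_sim
        assert len(reads) == c.n_reads
        assert set(truth.read_origin) == {r[0] for r in reads}
        assert set(truth.read_fate) == set(truth.read_origin)

    def test_reads_are_insert_plus_adapter(self, small_sim):
        c, refs, ests, planted, reads, truth = small_sim
        assert c.mutation_rate == 0
        for rid, seq, qual in reads[:200]:
            cls, src = truth.read_origin[rid]
            if cls == "miRNA":
                insert = refs["miRNA"][src]
                assert seq.startswith(insert)
                tail = seq[len(insert):]
                assert c.adapter3.startswith(tail) or \
                    tail.startswith(c.adapter3[:len(tail)])

    def test_byte_identical_fastq_for_same_config(self, tmp_path):
        c = cfg(n_reads=500)
        refs = make_reference_sets(c)
        ests, planted = make_est_collection(c)
        p1, p2 = tmp_path / "1.fq", tmp_path / "2.fq"
        simulate_library(c, refs, planted, str(p1))
        simulate_library(c, refs, planted, str(p2))
        assert p1.read_bytes() == p2.read_bytes()

    def test_modal_insert_length_is_24(self, small_sim):
        c, refs, ests, planted, reads, truth = small_sim
        from collections import Counter
        lengths = Counter()
        for rid, seq, qual in reads:
            if truth.read_origin[rid][0] == "background":
                insert = seq.split(c.adapter3[:6])[0]
                lengths[len(insert)] += 1
        assert lengths.most_common(1)[0][0] == 24


class TestPlantTargetSites:
    MIR = "ACGGATGCATTGAGGATCCA"

    @pytest.mark.parametrize("spec,expected", [
        (DefectSpec(), 0.0),
        (DefectSpec(wobbles=(10,)), 0.5),   # miRNA position 10 is T
        (DefectSpec(mismatches=(3,)), 1.5),
        (DefectSpec(mismatches=(15,)), 1.0),
        (DefectSpec(insertions=(8,)), 2.0),
    ])
    def test_declared_scores(self, spec, expected):
        rng = np.random.default_rng(4)
        site, score = build_target_site(self.MIR, spec, rng)
        assert score == expected

    def test_no_defect_site_is_reverse_complement(self):
        rng = np.random.default_rng(4)
        site, score = build_target_site(self.MIR, DefectSpec(), rng)
        assert site == revcomp(self.MIR)
        assert score == 0.0

    def test_position_outside_mirna_is_error(self):
        rng = np.random.default_rng(4)
        with pytest.raises(ValueError):
            build_target_site(self.MIR, DefectSpec(mismatches=(21,)), rng)

    def test_impossible_wobble_is_error(self):
        rng = np.random.default_rng(4)
        # position 1 is A: no G:U geometry exists
        with pytest.raises(ValueError):
            build_target_site(self.MIR, DefectSpec(wobbles=(1,)), rng)

    def test_planted_sites_recorded_and_scorable(self):
        rng = np.random.default_rng(6)
        tx = make_transcripts(3, 500, rng)
        mirnas = {"m1": self.MIR}
        specs = [("m1", "TX001", DefectSpec()),
                 ("m1", "TX002", DefectSpec(mismatches=(12,)))]
        modified, planted = plant_target_sites(tx, mirnas, specs, rng)
        assert [p.score for p in planted] == [0.0, 1.0]
        for p in planted:
            assert len(modified[p.transcript_id]) == len(tx[p.transcript_id])
        from srnamir.target_score import align_duplex
        for p in planted:
            best = align_duplex(self.MIR, modified[p.transcript_id])[0]
            assert best.total_score == p.score
            assert best.site_start == p.site_start
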