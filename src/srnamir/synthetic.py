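"""Synthetic small-RNA study generator with known ground truth.

Emulates a plant small-RNA sequencing experiment at desk scale: reference
sets for each RNA class, an EST collection with planted miRNA hairpin
precursors, a read library whose length distribution is dominated by the
24-nt and 21-nt classes, skewed known-miRNA family abundances, ncRNA
contaminants, 3'-adapter read-through, and transcripts carrying miRNA
target sites of controlled defect composition.  Every read and every
planted feature is recorded in a ground-truth object so recovery can be
tested exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from . import target_score as ts
from .discover import revcomp
from .target_score import Column, DEL_TARGET, INS_TARGET, MM, GU, WC, \
    DEFAULT_SCHEME, ScoringScheme, normalize_seq, pair_state, window_total

_BASES = np.array(list("ACGT"))
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

# Classic Solexa small-RNA adapters as documented default constants.
DEFAULT_ADAPTER3 = "TCGTATGCCGTCTTCTGCTTG"
DEFAULT_ADAPTER5 = "GTTCAGAGTTCTACAGTCCGACGATC"

# Read-length mixture dominated by the 24-nt (48%) and 21-nt (20.9%)
# classes, with the remaining mass spread over the 17-28 nt gel window.
DEFAULT_LENGTH_WEIGHTS = {
    17: 0.010, 18: 0.020, 19: 0.020, 20: 0.050, 21: 0.209, 22: 0.072,
    23: 0.077, 24: 0.480, 25: 0.025, 26: 0.015, 27: 0.012, 28: 0.010,
}

# Per-class read fractions mirroring the published category table
# (miRNA 9.52%, rRNA 4.08%, siRNA 8.85%, snRNA 0.02%, snoRNA 0.01%,
# tRNA 3.17%); planted-hairpin reads take 1% and the remainder is
# unannotated background.
DEFAULT_MIRNA_FRACTION = 0.0952
DEFAULT_CONTAMINANTS = {
    "rRNA": 0.0408, "siRNA": 0.0885, "snRNA": 0.0002,
    "snoRNA": 0.0001, "tRNA": 0.0317,
}
DEFAULT_HAIRPIN_FRACTION = 0.01
DEFAULT_CLASS_SIZES = {
    "miRNA": 30, "rRNA": 40, "tRNA": 30, "snRNA": 10, "snoRNA": 10,
    "siRNA": 60,
}
# Plant miRNA family numbers used for synthetic mature ids; abundance is
# skewed steeply across families as observed in real libraries.
_FAMILY_NUMBERS = (156, 166, 167, 169, 172, 319, 396, 398, 408, 2914)
_FAMILY_MEMBERS = (6, 5, 4, 4, 3, 2, 2, 2, 1, 1)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic library (defaults are the study conditions)."""

    seed: int = 0
    n_reads: int = 100_000
    length_weights: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_LENGTH_WEIGHTS))
    known_mirna_fraction: float = DEFAULT_MIRNA_FRACTION
    contaminant_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONTAMINANTS))
    hairpin_fraction: float = DEFAULT_HAIRPIN_FRACTION
    adapter3: str = DEFAULT_ADAPTER3
    adapter5: str = DEFAULT_ADAPTER5
    star_emission_prob: float = 0.25
    mutation_rate: float = 0.0
    low_quality_fraction: float = 0.05
    adapter_only_fraction: float = 0.03
    read_length: int = 36
    class_sizes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_SIZES))
    n_ests: int = 50
    est_length: tuple[int, int] = (400, 800)
    n_hairpins: int = 20
    family_skew: float = 2.5

    def validate(self) -> None:
        wsum = sum(self.length_weights.values())
        if abs(wsum - 1.0) > 1e-9:
            raise ValueError(f"length_weights must sum to 1 (got {wsum})")
        for length in self.length_weights:
            if not 17 <= length <= 30:
                raise ValueError(f"read length {length} outside 17-30 nt")
        total = (self.known_mirna_fraction + self.hairpin_fraction
                 + sum(self.contaminant_fractions.values()))
        if total > 1.0 + 1e-9:
            raise ValueError(f"class proportions sum to {total} > 1")
        for cls in self.contaminant_fractions:
            if self.class_sizes.get(cls, 0) == 0:
                raise ValueError(
                    f"class {cls!r} has a contaminant fraction but size 0")

    @property
    def background_fraction(self) -> float:
        return 1.0 - (self.known_mirna_fraction + self.hairpin_fraction
                      + sum(self.contaminant_fractions.values()))


@dataclass
class PlantedPrecursor:
    est_id: str
    offset: int  # 0-based offset of the mature sequence within the EST
    mature_seq: str  # DNA alphabet
    star_seq: str
    insert_start: int
    insert_length: int


@dataclass
class PlantedTarget:
    mirna_id: str
    transcript_id: str
    site_start: int  # 0-based half-open on the transcript sense strand
    site_end: int
    score: float
    wobbles: tuple[int, ...] = ()
    mismatches: tuple[int, ...] = ()
    insertions: tuple[int, ...] = ()


@dataclass
class GroundTruth:
    planted_precursors: list[PlantedPrecursor] = field(default_factory=list)
    planted_targets: list[PlantedTarget] = field(default_factory=list)
    read_origin: dict[str, tuple[str, str]] = field(default_factory=dict)
    # read_id -> (class label, source id); fates notes preprocess-visible fate
    read_fate: dict[str, str] = field(default_factory=dict)

    def class_counts(self, clean_only: bool = False) -> dict[str, int]:
        counts: dict[str, int] = {}
        for rid, (cls, _src) in self.read_origin.items():
            if clean_only and self.read_fate.get(rid) != "clean":
                continue
            counts[cls] = counts.get(cls, 0) + 1
        return counts


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def make_reference_sets(config: SimulationConfig
                        ) -> dict[str, dict[str, str]]:
    """Disjoint per-class reference collections (ids -> sequences).

    Mature miRNAs are 20-24 nt and named ``syn-miR<family><member>`` so
    family parsing is exercised; other classes are 18-28 nt.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    seen: set[str] = set()
    refs: dict[str, dict[str, str]] = {}

    def fresh(length: int) -> str:
        while True:
            seq = _random_seq(rng, length)
            if seq not in seen:
                seen.add(seq)
                return seq

    # mature miRNAs grouped into families
    n_mirna = config.class_sizes.get("miRNA", 0)
    if n_mirna < 1:
        raise ValueError("miRNA class size must be >= 1")
    mirnas: dict[str, str] = {}
    fam_idx = 0
    while len(mirnas) < n_mirna:
        fam = _FAMILY_NUMBERS[fam_idx % len(_FAMILY_NUMBERS)]
        members = _FAMILY_MEMBERS[fam_idx % len(_FAMILY_MEMBERS)]
        for m in range(members):
            if len(mirnas) >= n_mirna:
                break
            suffix = chr(ord("a") + m) if members > 1 else ""
            length = int(rng.integers(20, 25))
            mirnas[f"syn-miR{fam}{suffix}"] = fresh(length)
        fam_idx += 1
    refs["miRNA"] = mirnas

    for cls in ("rRNA", "tRNA", "snRNA", "snoRNA", "siRNA"):
        size = config.class_sizes.get(cls, 0)
        if size < 1:
            raise ValueError(f"class {cls!r} must have size >= 1")
        refs[cls] = {f"syn-{cls}-{i + 1}": fresh(int(rng.integers(18, 29)))
                     for i in range(size)}
    return refs


def write_fasta(sequences: dict[str, str], path: str) -> None:
    with open(path, "w") as fh:
        for rid in sequences:
            fh.write(f">{rid}\n{sequences[rid]}\n")


# ---------------------------------------------------------------------------
# Hairpin planting
# ---------------------------------------------------------------------------

def build_hairpin_insert(mature: str, rng: np.random.Generator,
                         target_length: Optional[int] = None,
                         loop_range: tuple[int, int] = (8, 40),
                         max_star_perturbations: int = 2
                         ) -> tuple[str, int, str]:
    """A stem-loop insert: a seamless perfect stem hosting the mature.

    The insert is ``stem5 + loop + revcomp(stem5)`` with ``stem5 = ext5 +
    mature``, so the hairpin folds unambiguously without consulting the
    folding engine; the star strand is the substring of the 3' arm implied
    by the duplex register with 2-nt 3' overhangs (those overhang bases
    stay paired inside the precursor, exactly as in real pre-miRNAs, and
    become overhangs only on excision).  The 3' arm is perturbed at up to
    ``max_star_perturbations`` interior duplex positions, each unpairing
    one mature base.  The loop is A/C-biased to keep it from competing
    with the stem.  Returns ``(insert, mature_offset, star_seq)``.
    """
    mature = normalize_seq(mature)
    L = len(mature)
    if not 20 <= L <= 24:
        raise ValueError(f"mature must be 20-24 nt (got {L})")
    if target_length is None:
        target_length = _draw_precursor_length(rng)
    lo, hi = loop_range
    loop_len = int(rng.integers(lo, hi + 1))
    loop_len = min(loop_len, max(lo, target_length - 2 * L - 6))
    if (target_length - 2 * L - loop_len) % 2:
        loop_len += 1
    ext = max((target_length - 2 * L - loop_len) // 2, 4)

    ext5 = _random_seq(rng, ext)
    loop = "".join(rng.choice(np.array(list("AACCAC")), size=loop_len))
    stem5 = ext5 + mature
    arm3 = list(revcomp(stem5))
    n = 2 * len(stem5) + loop_len  # insert length
    e = ext  # mature occupies [e, e+L)
    q = len(stem5) + loop_len  # 3' arm start within insert
    # perturb interior duplex positions (pairing mature bases 3..L-3)
    k = int(rng.integers(0, max_star_perturbations + 1))
    if k:
        # 3' arm index j pairs insert position n-1-j... relative: arm3[j]
        # pairs stem5[len(stem5)-1-j]; mature interior corresponds to
        # j in [2+2, L-3] shifted by nothing (arm3[0] pairs mature 3' end)
        choices = np.arange(4, L - 3)
        positions = rng.choice(choices, size=min(k, choices.size),
                               replace=False)
        for j in positions:
            mature_base = mature[L - 1 - int(j)]
            bad = {_COMP[mature_base]}
            if mature_base == "G":
                bad.add("T")
            if mature_base == "T":
                bad.add("G")
            arm3[int(j)] = str(rng.choice([b for b in "ACGT"
                                           if b not in bad]))
    insert = stem5 + loop + "".join(arm3)
    # star by duplex register: partner(mature_end-3) .. partner(mature_start)+3
    star = insert[n - e - L + 2:n - e + 2]
    return insert, e, star


def _draw_precursor_length(rng: np.random.Generator) -> int:
    # most precursors fall in the 75-188 nt band; a minority are longer
    if rng.random() < 0.88:
        return int(rng.integers(80, 187))
    return int(rng.integers(189, 320))


def plant_hairpin(est: str, mature: str, rng: np.random.Generator,
                  target_length: Optional[int] = None
                  ) -> tuple[str, int, str]:
    """Overwrite a segment of an EST with a stem-loop insert.

    Returns ``(modified_est, mature_offset, star_seq)``; the mature
    sequence occurs verbatim at the returned offset.
    """
    est = normalize_seq(est)
    insert, mature_off, star = build_hairpin_insert(mature, rng,
                                                    target_length)
    if len(est) < len(insert):
        raise ValueError(
            f"EST ({len(est)} nt) too short to host a {len(insert)} nt insert")
    offset = int(rng.integers(0, len(est) - len(insert) + 1))
    modified = est[:offset] + insert + est[offset + len(insert):]
    return modified, offset + mature_off, star


def make_est_collection(config: SimulationConfig,
                        rng: Optional[np.random.Generator] = None
                        ) -> tuple[dict[str, str], list[PlantedPrecursor]]:
    """Random ESTs with hairpin precursors planted in the first few."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    ests = {}
    lo, hi = config.est_length
    for i in range(config.n_ests):
        ests[f"EST{i + 1:04d}"] = _random_seq(rng, int(rng.integers(lo, hi)))
    planted: list[PlantedPrecursor] = []
    est_ids = sorted(ests)
    for h in range(config.n_hairpins):
        est_id = est_ids[h % len(est_ids)]
        mature = _random_seq(rng, int(rng.integers(20, 25)))
        est = ests[est_id]
        insert, mature_off, star = build_hairpin_insert(mature, rng)
        if len(est) < len(insert):
            raise ValueError(f"EST {est_id} too short for a planted hairpin")
        offset = int(rng.integers(0, len(est) - len(insert) + 1))
        ests[est_id] = est[:offset] + insert + est[offset + len(insert):]
        planted.append(PlantedPrecursor(est_id, offset + mature_off, mature,
                                        star, insert_start=offset,
                                        insert_length=len(insert)))
    return ests, planted


# ---------------------------------------------------------------------------
# Read library
# ---------------------------------------------------------------------------

def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = str(rng.choice([b for b in "ACGT" if b != out[i]]))
    return "".join(out)


def simulate_library(config: SimulationConfig,
                     references: dict[str, dict[str, str]],
                     planted: Sequence[PlantedPrecursor],
                     fastq_path: Optional[str] = None
                     ) -> tuple[list[tuple[str, str, str]], GroundTruth]:
    """Generate the read library and its ground truth.

    Every read is ``insert + 3' adapter`` truncated to the read length;
    class mixture, family skew, star emission, low-quality overlay and
    adapter-only contamination follow the configuration.  Returns the list
    of ``(read_id, sequence, quality)`` records (also written to
    ``fastq_path`` when given) and the GroundTruth.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 2)
    truth = GroundTruth()

    classes = ["miRNA"] + sorted(config.contaminant_fractions) + [
        "hairpin", "background"]
    probs = [config.known_mirna_fraction] + [
        config.contaminant_fractions[c]
        for c in sorted(config.contaminant_fractions)] + [
        config.hairpin_fraction, config.background_fraction]

    mirna_ids = sorted(references["miRNA"])
    fam_weights = _family_weights(mirna_ids, config.family_skew)
    lengths = np.array(sorted(config.length_weights))
    length_p = np.array([config.length_weights[int(l)] for l in lengths])
    length_p = length_p / length_p.sum()
    ref_seqs = {seq for seqs in references.values() for seq in seqs.values()}
    planted_seqs = {p.mature_seq for p in planted} | {p.star_seq
                                                      for p in planted}
    adapter_tail = (config.adapter3 + DEFAULT_ADAPTER5
                    + config.adapter3)  # read-through filler

    reads: list[tuple[str, str, str]] = []
    class_draws = rng.choice(len(classes), size=config.n_reads, p=probs)
    for i in range(config.n_reads):
        read_id = f"read{i + 1:06d}"
        fate = "clean"
        if rng.random() < config.adapter_only_fraction:
            cls, src, insert = "adapter", "", ""
            fate = "adapter_only"
        else:
            cls = classes[int(class_draws[i])]
            if cls == "miRNA":
                src = mirna_ids[int(rng.choice(len(mirna_ids),
                                               p=fam_weights))]
                insert = references["miRNA"][src]
            elif cls == "hairpin":
                p = planted[int(rng.integers(0, len(planted)))]
                if rng.random() < config.star_emission_prob:
                    insert, src = p.star_seq, f"{p.est_id}:star"
                else:
                    insert, src = p.mature_seq, f"{p.est_id}:mature"
            elif cls == "background":
                src = ""
                while True:
                    insert = _random_seq(
                        rng, int(lengths[rng.choice(len(lengths),
                                                    p=length_p)]))
                    if insert not in ref_seqs and insert not in planted_seqs:
                        break
            else:
                src = sorted(references[cls])[
                    int(rng.integers(0, len(references[cls])))]
                insert = references[cls][src]
            insert = _mutate(insert, config.mutation_rate, rng)
            if len(insert) < 18:
                fate = "too_short"
        read = (insert + adapter_tail)[:config.read_length]
        if fate != "adapter_only" and rng.random() < config.low_quality_fraction:
            qual = "#" * len(read)
            fate = "low_quality"
        else:
            qual = "I" * len(read)
        reads.append((read_id, read, qual))
        truth.read_origin[read_id] = (cls, src)
        truth.read_fate[read_id] = fate
    truth.planted_precursors = list(planted)
    if fastq_path:
        write_fastq(reads, fastq_path)
    return reads, truth


def _family_weights(mirna_ids: Sequence[str], skew: float) -> np.ndarray:
    from .classify import family_name
    families = sorted({family_name(mid) for mid in mirna_ids})
    fam_w = {fam: (rank + 1) ** -skew for rank, fam in enumerate(families)}
    w = np.array([fam_w[family_name(mid)] for mid in mirna_ids])
    return w / w.sum()


def write_fastq(reads: Sequence[tuple[str, str, str]], path: str) -> None:
    with open(path, "w") as fh:
        for read_id, seq, qual in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{qual}\n")


def write_ground_truth(truth: GroundTruth, tsv_path: str,
                       json_path: str) -> None:
    """Read origins as TSV; planted features as a JSON sidecar."""
    with open(tsv_path, "w") as fh:
        fh.write("read_id\tclass\tsource_id\tfate\n")
        for rid in sorted(truth.read_origin):
            cls, src = truth.read_origin[rid]
            fh.write(f"{rid}\t{cls}\t{src}\t{truth.read_fate.get(rid, '')}\n")
    payload = {
        "planted_precursors": [asdict(p) for p in truth.planted_precursors],
        "planted_targets": [asdict(t) for t in truth.planted_targets],
    }
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# Target-site planting
# ---------------------------------------------------------------------------

_WOBBLE_TARGET = {"G": "T", "T": "G"}


@dataclass(frozen=True)
class DefectSpec:
    """Controlled defects of one planted target site.

    Positions are 1-based from the miRNA 5' end; ``insertions`` lists
    miRNA positions after which an extra target base is inserted.
    """

    wobbles: tuple[int, ...] = ()
    mismatches: tuple[int, ...] = ()
    insertions: tuple[int, ...] = ()


def build_target_site(mirna: str, spec: DefectSpec,
                      rng: np.random.Generator,
                      scheme: ScoringScheme = DEFAULT_SCHEME
                      ) -> tuple[str, float]:
    """Target-site sequence realizing a defect spec, plus its exact score.

    The score is computed through the scoring statistic itself (windowed),
    so the declared ground-truth score is by construction the score the
    pipeline reproduces.
    """
    mirna = normalize_seq(mirna)
    L = len(mirna)
    for p in spec.wobbles + spec.mismatches + spec.insertions:
        if not 1 <= p <= L:
            raise ValueError(f"defect position {p} outside miRNA length {L}")
    if set(spec.wobbles) & set(spec.mismatches):
        raise ValueError("a position cannot be both wobble and mismatch")
    site = list(revcomp(mirna))  # site index L-p pairs miRNA position p
    for p in spec.wobbles:
        m = mirna[p - 1]
        if m not in _WOBBLE_TARGET:
            raise ValueError(f"no G:U wobble possible at position {p} "
                             f"(miRNA base {m})")
        site[L - p] = _WOBBLE_TARGET[m]
    for p in spec.mismatches:
        m = mirna[p - 1]
        bad = {_COMP[m], _WOBBLE_TARGET.get(m, "")}
        site[L - p] = str(rng.choice([b for b in "ACGT" if b not in bad]))
    for p in sorted(spec.insertions):  # descending site index
        if p == L:
            raise ValueError("insertions must fall between miRNA positions")
        site.insert(L - p, str(rng.choice(list("ACGT"))))
    site_seq = "".join(site)
    cols = _spec_columns(mirna, site_seq, spec)
    score, _ = window_total(cols, scheme)
    return site_seq, score


def _spec_columns(mirna: str, site: str, spec: DefectSpec) -> tuple[Column, ...]:
    rev = site[::-1]
    L = len(mirna)
    cols: list[Column] = []
    j = 0
    ins_after = sorted(spec.insertions)
    for i in range(L):
        cols.append(Column(pair_state(mirna[i], rev[j]), i + 1))
        j += 1
        if i + 1 in ins_after:
            cols.append(Column(INS_TARGET, None, after_pos=i + 1))
            j += 1
    return tuple(cols)


def plant_target_sites(transcripts: dict[str, str],
                       mirnas: dict[str, str],
                       defect_specs: Sequence[tuple[str, str, DefectSpec]],
                       rng: np.random.Generator,
                       scheme: ScoringScheme = DEFAULT_SCHEME
                       ) -> tuple[dict[str, str], list[PlantedTarget]]:
    """Embed one site per (mirna_id, transcript_id, spec) triple.

    Sites are placed at non-overlapping random offsets (overwriting the
    transcript segment) and recorded with their exact windowed score.
    """
    out = {tid: normalize_seq(seq) for tid, seq in transcripts.items()}
    occupied: dict[str, list[tuple[int, int]]] = {t: [] for t in out}
    planted: list[PlantedTarget] = []
    for mirna_id, transcript_id, spec in defect_specs:
        mirna = normalize_seq(mirnas[mirna_id])
        site, score = build_target_site(mirna, spec, rng, scheme)
        tx = out[transcript_id]
        if len(tx) < len(site):
            raise ValueError(f"transcript {transcript_id} shorter than site")
        for _ in range(200):
            start = int(rng.integers(0, len(tx) - len(site) + 1))
            span = (start - len(mirna) - 2, start + len(site) + len(mirna) + 2)
            if all(span[1] <= s or span[0] >= e
                   for s, e in occupied[transcript_id]):
                break
        else:
            raise ValueError(f"could not place site on {transcript_id}")
        occupied[transcript_id].append(span)
        out[transcript_id] = tx[:start] + site + tx[start + len(site):]
        planted.append(PlantedTarget(mirna_id, transcript_id, start,
                                     start + len(site), score,
                                     spec.wobbles, spec.mismatches,
                                     spec.insertions))
    return out, planted


def make_transcripts(n: int, length: int, rng: np.random.Generator
                     ) -> dict[str, str]:
    return {f"TX{i + 1:03d}": _random_seq(rng, length) for i in range(n)}
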