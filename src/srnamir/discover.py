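"""Novel miRNA discovery from EST-mapped tags by hairpin evaluation.

Unannotated tags are exactly matched against an EST collection; around
each hit a +/-150 nt context window is extracted and folded to its single
lowest-energy structure.  A candidate is retained when the putative mature
sequence sits wholly within one arm of a stem-loop, pairs against the
opposite arm with at most 4 unpaired mature bases and no asymmetric bulge
larger than 2 nt, does not span the terminal loop, and folds with negative
energy — the classical plant-miRNA annotation criteria.  The miRNA* strand
implied by the duplex (2-nt 3' overhangs) is searched among the sequenced
tags as star-read support.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .fold import fold_mfe, pair_table
from .preprocess import SmallRNATag
from .target_score import normalize_seq

DEFAULT_FLANK = 150
REVCOMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return normalize_seq(seq).translate(REVCOMP)[::-1]


@dataclass(frozen=True)
class DuplexCriteria:
    """Hairpin/duplex acceptance constants for novel miRNA annotation."""

    max_unpaired_mature: int = 4
    max_bulge: int = 2
    overhang: int = 2
    min_precursor: int = 50
    max_precursor: int = 350
    min_mature: int = 20
    max_mature: int = 24

    def __post_init__(self) -> None:
        if min(self.max_unpaired_mature, self.max_bulge, self.overhang,
               self.min_precursor, self.max_precursor) < 0:
            raise ValueError("criteria must be non-negative")


@dataclass
class PrecursorCandidate:
    """An accepted hairpin: mature/star sequences, structure, energy."""

    name: str
    mature_seq: str  # RNA alphabet
    mature_count: int
    est_id: str
    precursor_seq: str  # RNA alphabet
    structure: str
    mfe: float
    arm: str  # "5p" or "3p"
    mature_offset: int  # 0-based within precursor
    star_seq: Optional[str] = None
    star_count: int = 0
    star_supported: bool = False
    star_offset: Optional[int] = None

    @property
    def precursor_length(self) -> int:
        return len(self.precursor_seq)

    def validate(self) -> None:
        if len(self.precursor_seq) != len(self.structure):
            raise AssertionError("structure/sequence length mismatch")
        pair_table(self.structure)  # raises when unbalanced
        if self.mfe > 0:
            raise AssertionError("accepted candidate with positive energy")
        mstart = self.mature_offset
        if self.precursor_seq[mstart:mstart + len(self.mature_seq)] \
                != self.mature_seq:
            raise AssertionError("mature sequence not at recorded offset")


@dataclass
class Rejection:
    est_id: str
    offset: int
    reason: str
    detail: str = ""


class RejectedCandidate(Exception):
    def __init__(self, reason: str, detail: str = ""):
        super().__init__(reason)
        self.reason = reason
        self.detail = detail


def map_to_ests(tag: str, ests: dict[str, str]
                ) -> list[tuple[str, int, str]]:
    """All exact occurrences of a tag (or its reverse complement) in ESTs.

    Returns (est_id, offset, strand) with 0-based plus-strand offsets of
    the occurrence's half-open span start.
    """
    tag = normalize_seq(tag)
    rc = revcomp(tag)
    hits = []
    for est_id in sorted(ests):
        seq = normalize_seq(ests[est_id])
        for query, strand in ((tag, "+"), (rc, "-")):
            if strand == "-" and rc == tag:
                continue  # palindromic tag: avoid duplicate records
            start = seq.find(query)
            while start != -1:
                hits.append((est_id, start, strand))
                start = seq.find(query, start + 1)
    hits.sort()
    return hits


def extract_context(est: str, hit: tuple[str, int, str], tag_length: int,
                    flank: int = DEFAULT_FLANK) -> tuple[str, int]:
    """+/-``flank`` nt context around a hit; minus hits reverse-complemented.

    Returns ``(window, tag_start_in_window)`` with the tag position given
    on the window as returned (already re-oriented for minus hits).
    """
    est = normalize_seq(est)
    _, start, strand = hit
    end = start + tag_length
    lo = max(0, start - flank)
    hi = min(len(est), end + flank)
    window = est[lo:hi]
    if strand == "+":
        return window, start - lo
    return revcomp(window), hi - end


def _mature_pairing(partner: list[Optional[int]], ts: int, te: int
                    ) -> tuple[list[int], str]:
    """Paired mature positions (0-based) and the arm; raises on loop overlap."""
    paired = [i for i in range(ts, te) if partner[i] is not None]
    if not paired:
        raise RejectedCandidate("unpaired_mature", "no mature base pairs")
    partners = [partner[i] for i in paired]
    inside = [p for p in partners if ts <= p < te]
    if inside:
        raise RejectedCandidate("loop_overlap", "mature pairs with itself")
    before = [p for p in partners if p < ts]
    after = [p for p in partners if p >= te]
    if before and after:
        raise RejectedCandidate("loop_overlap", "mature spans the terminal loop")
    arm = "5p" if after else "3p"
    # a mature tail reaching into the terminal loop: the region between the
    # innermost paired mature base and its partner holds no pairs at all
    if arm == "5p":
        i_max = paired[-1]
        lo, hi = i_max, partner[i_max]
        tail = te - 1 > i_max
    else:
        i_min = paired[0]
        lo, hi = partner[i_min], i_min
        tail = ts < i_min
    if tail and not any(partner[q] is not None for q in range(lo + 1, hi)):
        raise RejectedCandidate("loop_overlap",
                                "mature extends into the terminal loop")
    return paired, arm


def evaluate_candidate(window: str, tag_start: int, tag_length: int,
                       structure: str, mfe: float,
                       criteria: DuplexCriteria = DuplexCriteria(),
                       est_id: str = "", mature_count: int = 0,
                       name: str = "candidate") -> PrecursorCandidate:
    """Apply the duplex criteria to a folded window; raises RejectedCandidate.

    The window is typically a trimmed precursor; ``tag_start`` locates the
    putative mature sequence within it (0-based).
    """
    window = normalize_seq(window)
    ts, te = tag_start, tag_start + tag_length
    if not (0 <= ts < te <= len(window)):
        raise ValueError("tag position outside window")
    if not criteria.min_mature <= tag_length <= criteria.max_mature:
        raise RejectedCandidate("mature_length",
                                f"{tag_length} nt outside 20-24")
    if len(structure) != len(window):
        raise ValueError("structure does not correspond to window")
    if mfe >= 0:
        raise RejectedCandidate("nonnegative_mfe", f"mfe={mfe}")
    partner = pair_table(structure)
    paired, arm = _mature_pairing(partner, ts, te)
    n_unpaired = tag_length - len(paired)
    if n_unpaired > criteria.max_unpaired_mature:
        raise RejectedCandidate(
            "excess_mismatch",
            f"{n_unpaired} unpaired mature bases > {criteria.max_unpaired_mature}")
    # asymmetric bulges between consecutive paired mature bases
    for i1, i2 in zip(paired, paired[1:]):
        p1, p2 = partner[i1], partner[i2]
        gap_m = i2 - i1 - 1
        gap_s = p1 - p2 - 1
        if p2 >= p1:  # nesting implies partners descend with mature index
            raise RejectedCandidate("nonlinear_duplex",
                                    "crossing pairs within mature span")
        if abs(gap_m - gap_s) > criteria.max_bulge:
            raise RejectedCandidate(
                "bulge", f"asymmetric bulge {abs(gap_m - gap_s)} nt "
                         f"> {criteria.max_bulge}")
    if not criteria.min_precursor <= len(window) <= criteria.max_precursor:
        raise RejectedCandidate("precursor_length",
                                f"{len(window)} nt outside "
                                f"[{criteria.min_precursor}, {criteria.max_precursor}]")
    return PrecursorCandidate(
        name=name,
        mature_seq=window[ts:te].replace("T", "U"),
        mature_count=mature_count,
        est_id=est_id,
        precursor_seq=window.replace("T", "U"),
        structure=structure,
        mfe=mfe,
        arm=arm,
        mature_offset=ts,
    )


def infer_star(window: str, structure: str, tag_start: int, tag_length: int,
               overhang: int = 2) -> Optional[tuple[int, int]]:
    """Star-strand span implied by the duplex with 2-nt 3' overhangs.

    Returns a 0-based half-open span on the window, or None when the
    structure provides no usable duplex.  In a duplex with 2-nt 3'
    overhangs the star 5' end pairs the mature base ``overhang`` positions
    inside the mature 3' end, and the star 3' end extends ``overhang`` nt
    past the partner of the mature 5' end; both relations hold on either
    arm because pairing is nested.
    """
    partner = pair_table(structure)
    ts, te = tag_start, tag_start + tag_length
    n = len(window)
    # star 5' end: partner of mature base te-1-overhang (scan inward on no pair)
    s_start = None
    for idx in range(te - 1 - overhang, ts - 1, -1):
        p = partner[idx]
        if p is not None:
            s_start = p - ((te - 1 - overhang) - idx)
            break
    # star 3' end: partner of mature 5' end plus the star's own overhang
    s_end = None
    for idx in range(ts, te):
        p = partner[idx]
        if p is not None:
            s_end = p + (idx - ts) + overhang + 1
            break
    if s_start is None or s_end is None or s_end <= s_start:
        return None
    s_start = max(0, s_start)
    s_end = min(n, s_end)
    if s_end - s_start < 15:
        return None
    return s_start, s_end


def detect_star(candidate: PrecursorCandidate,
                tag_counts: dict[str, int],
                overhang: int = 2) -> PrecursorCandidate:
    """Fill star_seq/star_count from the structure and sequenced tags.

    The star sequence is read off the precursor at the duplex-implied span;
    its count is the abundance of a tag matching it exactly (else 0 and
    flagged unsupported).
    """
    window = candidate.precursor_seq.replace("U", "T")
    span = infer_star(window, candidate.structure, candidate.mature_offset,
                      len(candidate.mature_seq), overhang)
    if span is None:
        return candidate
    s_start, s_end = span
    star_dna = window[s_start:s_end]
    count = tag_counts.get(star_dna, 0)
    candidate.star_seq = star_dna.replace("T", "U")
    candidate.star_count = count
    candidate.star_supported = count > 0
    candidate.star_offset = s_start
    return candidate


def trim_precursor(window: str, structure: str, ts: int, te: int,
                   star_span: Optional[tuple[int, int]],
                   max_gap: int = 3) -> tuple[int, int]:
    """Smallest window holding the mature-star duplex plus its closing stem.

    Extends outward from the duplex bounds through the enclosing helix,
    tolerating bulges/loops of up to ``max_gap`` nt, and returns a 0-based
    half-open span on the window.
    """
    partner = pair_table(structure)
    n = len(window)
    if star_span is not None:
        a = min(ts, star_span[0])
        b = max(te, star_span[1]) - 1
    else:
        a, b = ts, te - 1
    changed = True
    while changed:
        changed = False
        for x in range(a - 1, max(-1, a - 1 - max_gap), -1):
            y = partner[x]
            if y is not None and b <= y <= b + max_gap + 1:
                a, b = x, y
                changed = True
                break
    return a, b + 1


@dataclass
class DiscoveryResult:
    candidates: list[PrecursorCandidate]
    rejections: list[Rejection]

    def table(self) -> pd.DataFrame:
        rows = []
        for c in self.candidates:
            rows.append((c.name, c.mature_count, c.mature_seq,
                         len(c.mature_seq), c.est_id, c.precursor_length,
                         round(c.mfe, 2)))
            if c.star_supported:
                rows.append((c.name + "*", c.star_count, c.star_seq,
                             len(c.star_seq), c.est_id, c.precursor_length,
                             round(c.mfe, 2)))
        return pd.DataFrame(rows, columns=["name", "count", "sequence",
                                           "length", "est_id",
                                           "precursor_length",
                                           "folding_energy"])


def discover_mirnas(tags: Sequence[SmallRNATag], ests: dict[str, str],
                    criteria: DuplexCriteria = DuplexCriteria(),
                    engine: str = "auto", flank: int = DEFAULT_FLANK
                    ) -> DiscoveryResult:
    """Full discovery pass over a tag set (normally the unannotated tags).

    For each EST hit: extract the context window, fold it, locate and trim
    the hairpin, refold the trimmed precursor, apply the duplex criteria,
    and search tag support for the implied star strand.  Candidates are
    deduplicated by precursor sequence and named in order of discovery.
    """
    tags = sorted(tags, key=lambda t: (-t.count, t.sequence))
    tag_counts = {t.sequence: t.count for t in tags}
    candidates: list[PrecursorCandidate] = []
    rejections: list[Rejection] = []
    by_est: dict[str, list[PrecursorCandidate]] = {}
    # fast pre-screen: one concatenated text spares a per-EST scan per tag
    haystack = "#".join(normalize_seq(s) for s in ests.values())
    for tag in tags:
        if not criteria.min_mature <= tag.length <= criteria.max_mature:
            continue
        if tag.sequence not in haystack and revcomp(tag.sequence) not in haystack:
            continue
        for hit in map_to_ests(tag.sequence, ests):
            est_id, offset, strand = hit
            window, ts = extract_context(ests[est_id], hit, tag.length, flank)
            try:
                candidate = _evaluate_locus(window, ts, tag, est_id,
                                            criteria, engine)
            except RejectedCandidate as rej:
                rejections.append(Rejection(est_id, offset, rej.reason,
                                            rej.detail))
                continue
            candidate = detect_star(candidate, tag_counts, criteria.overhang)
            merged = False
            for prev in by_est.get(est_id, ()):
                same_precursor = prev.precursor_seq == candidate.precursor_seq
                # a hairpin is (near-)self-reverse-complementary: the same
                # mature also hits the minus strand of its own EST
                same_mature = prev.mature_seq == candidate.mature_seq
                is_star_locus = (prev.star_seq == candidate.mature_seq
                                 or prev.mature_seq == candidate.star_seq)
                if same_precursor or same_mature or is_star_locus:
                    # second locus of a hairpin already reported (typically
                    # reached via its star strand): fold in star support
                    if (prev.star_seq == candidate.mature_seq
                            and candidate.mature_count > prev.star_count):
                        prev.star_count = candidate.mature_count
                        prev.star_supported = True
                    merged = True
                    break
            if merged:
                continue
            by_est.setdefault(est_id, []).append(candidate)
            candidates.append(candidate)
    # name candidates by descending mature abundance, then sequence
    candidates.sort(key=lambda c: (-c.mature_count, c.mature_seq))
    for i, cand in enumerate(candidates, 1):
        cand.name = f"miR-novel{i}"
    return DiscoveryResult(candidates, rejections)


def _evaluate_locus(window: str, ts: int, tag: SmallRNATag, est_id: str,
                    criteria: DuplexCriteria, engine: str
                    ) -> PrecursorCandidate:
    structure, mfe = fold_mfe(window, engine)
    if mfe >= 0:
        raise RejectedCandidate("nonnegative_mfe", f"mfe={mfe}")
    partner = pair_table(structure)
    te = ts + tag.length
    _mature_pairing(partner, ts, te)  # raises loop_overlap early
    star_span = infer_star(window, structure, ts, tag.length,
                           criteria.overhang)
    a, b = trim_precursor(window, structure, ts, te, star_span)
    precursor = window[a:b]
    structure2, mfe2 = fold_mfe(precursor, engine)
    return evaluate_candidate(precursor, ts - a, tag.length, structure2,
                              mfe2, criteria, est_id=est_id,
                              mature_count=tag.count)


def summarize_novel(table: pd.DataFrame,
                    band: tuple[int, int] = (75, 188),
                    high_reads: int = 1000, low_reads: int = 10) -> dict:
    """Summary statistics over a novel-candidate table.

    Folding-energy statistics run over all rows (star rows included);
    the precursor-length band fraction runs over unique precursors; the
    read-threshold counts run over family (non-star) rows, with strict
    inequalities.
    """
    if table.empty:
        raise ValueError("cannot summarize an empty candidate table")
    energies = table["folding_energy"].astype(float)
    star = table["name"].str.endswith("*")
    families = table[~star]
    uniq = table.drop_duplicates(subset=["est_id", "precursor_length"])
    lengths = uniq["precursor_length"].astype(int)
    in_band = ((lengths >= band[0]) & (lengths <= band[1])).sum()
    return {
        "n_rows": int(len(table)),
        "n_families": int(len(families)),
        "n_star_supported": int(star.sum()),
        "mean_mfe": round(float(energies.mean()), 2),
        "min_mfe": float(energies.min()),
        "max_mfe": float(energies.max()),
        "min_precursor_length": int(lengths.min()),
        "max_precursor_length": int(lengths.max()),
        "band_fraction": float(in_band / len(uniq)),
        "n_high_read_families": int((families["count"].astype(int)
                                     > high_reads).sum()),
        "n_low_read_families": int((families["count"].astype(int)
                                    < low_reads).sum()),
        "max_count": int(table["count"].astype(int).max()),
    }
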