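"""Point-based miRNA target prediction by duplex complementarity scoring.

A miRNA is aligned antiparallel against every position of a candidate
transcript.  Each alignment column is classified by its pairing state and
penalized:

* Watson–Crick pair           0.0 points
* G:U wobble pair             0.5 points
* other non-canonical pair    1.0 points
* indel (either strand)       2.0 points

Mismatches (but not wobbles) falling in the seed region — miRNA positions
2–7 counted 1-based from the 5' end — carry an extra 0.5-point surcharge.
For miRNAs longer than 20 nt the total score is the minimum over all
windows of 20 consecutive miRNA positions (seed positions keep their
numbering on the full miRNA).  A site is called a target when its total
score is strictly below 3.0 points.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

# Column pairing states
WC = "WC"
GU = "GU"
MM = "MM"
INS_TARGET = "INS_target"  # extra transcript base, no miRNA position
DEL_TARGET = "DEL_target"  # bulged miRNA base, no transcript base

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_ENC = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}
_COMP_CODE = np.array([3, 2, 1, 0], dtype=np.int8)


def normalize_seq(seq: str) -> str:
    """Upper-case and collapse the RNA alphabet onto DNA (U -> T)."""
    return seq.upper().replace("U", "T")


def encode(seq: str) -> np.ndarray:
    try:
        return np.array([_ENC[c] for c in normalize_seq(seq)], dtype=np.int8)
    except KeyError as exc:  # pragma: no cover - defensive
        raise ValueError(f"non-ACGTU symbol in sequence: {exc}") from None


@dataclass(frozen=True)
class ScoringScheme:
    """Penalty constants and thresholds of the target-prediction statistic."""

    wobble_penalty: float = 0.5
    noncanonical_penalty: float = 1.0
    indel_penalty: float = 2.0
    seed_extra_penalty: float = 0.5
    seed_range: tuple[int, int] = (2, 7)  # 1-based inclusive, miRNA 5' end
    window: int = 20
    accept_below: float = 3.0

    def __post_init__(self) -> None:
        for name in ("wobble_penalty", "noncanonical_penalty",
                     "indel_penalty", "seed_extra_penalty"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        lo, hi = self.seed_range
        if lo < 1 or hi < lo:
            raise ValueError("seed_range must be a valid 1-based interval")


DEFAULT_SCHEME = ScoringScheme()


@dataclass(frozen=True)
class Column:
    """One alignment column: pairing state plus 1-based miRNA position.

    ``mirna_pos`` is None for target-insertion columns; for those,
    ``after_pos`` names the miRNA position the insertion follows.
    """

    state: str
    mirna_pos: Optional[int] = None
    after_pos: Optional[int] = None


@dataclass
class DuplexAlignment:
    """A miRNA-transcript duplex with its penalty breakdown."""

    mirna_id: str
    transcript_id: str
    site_start: int  # 0-based half-open, transcript sense strand
    site_end: int
    columns: tuple[Column, ...]
    total_score: float
    raw_scores: tuple[float, ...] = ()  # per-window scores

    @property
    def n_indels(self) -> int:
        return sum(c.state in (INS_TARGET, DEL_TARGET) for c in self.columns)


@dataclass
class TargetHit:
    alignment: DuplexAlignment
    accepted: bool
    annotation: Optional[str] = None


def pair_state(mirna_base: str, target_base: str) -> str:
    """Classify the pairing of a miRNA base against a transcript sense base."""
    m = normalize_seq(mirna_base)
    t = normalize_seq(target_base)
    if t == _COMPLEMENT[m]:
        return WC
    if (m, t) in (("G", "T"), ("T", "G")):
        return GU
    return MM


def _column_penalty(col: Column, scheme: ScoringScheme) -> float:
    if col.state == WC:
        return 0.0
    if col.state == GU:
        return scheme.wobble_penalty
    if col.state == MM:
        pen = scheme.noncanonical_penalty
        lo, hi = scheme.seed_range
        if col.mirna_pos is not None and lo <= col.mirna_pos <= hi:
            pen += scheme.seed_extra_penalty
        return pen
    if col.state in (INS_TARGET, DEL_TARGET):
        return scheme.indel_penalty
    raise ValueError(f"unknown column state: {col.state!r}")


def score_alignment(columns: Sequence[Column],
                    scheme: ScoringScheme = DEFAULT_SCHEME) -> float:
    """Sum the per-column penalties over a full alignment (no windowing)."""
    return sum(_column_penalty(c, scheme) for c in columns)


def window_total(columns: Sequence[Column],
                 scheme: ScoringScheme = DEFAULT_SCHEME
                 ) -> tuple[float, tuple[float, ...]]:
    """Minimum score over all consecutive 20-miRNA-position windows.

    Returns ``(total, per_window_scores)``.  Seed positions are numbered on
    the full miRNA; insertion columns are charged to windows containing both
    flanking miRNA positions.
    """
    positions = [c.mirna_pos for c in columns if c.mirna_pos is not None]
    if not positions:
        raise ValueError("alignment has no miRNA positions")
    length = max(positions)
    if length <= scheme.window:
        total = score_alignment(columns, scheme)
        return total, (total,)
    scores = []
    for w in range(1, length - scheme.window + 2):
        lo, hi = w, w + scheme.window - 1
        s = 0.0
        for col in columns:
            if col.mirna_pos is not None:
                if lo <= col.mirna_pos <= hi:
                    s += _column_penalty(col, scheme)
            else:  # insertion: needs both flanks inside the window
                g = col.after_pos
                if g is not None and lo <= g and g + 1 <= hi:
                    s += _column_penalty(col, scheme)
        scores.append(s)
    return min(scores), tuple(scores)


# ---------------------------------------------------------------------------
# Duplex search
# ---------------------------------------------------------------------------

def build_columns(mirna: str, site: str,
                  gap: Optional[tuple[str, int]] = None) -> tuple[Column, ...]:
    """Construct alignment columns for a miRNA against a target site.

    ``site`` is the transcript sense-strand subsequence, 5'->3'; the miRNA
    pairs antiparallel (miRNA position 1 against the site's 3' end).  ``gap``
    is None for the ungapped duplex, ``("del", d)`` for a target gap opposite
    miRNA position ``d`` (1-based), or ``("ins", g)`` for an extra target
    base between miRNA positions ``g`` and ``g+1``.
    """
    m = normalize_seq(mirna)
    rev = normalize_seq(site)[::-1]  # rev[j] pairs miRNA position j+1
    L = len(m)
    cols: list[Column] = []
    if gap is None:
        if len(rev) != L:
            raise ValueError("ungapped site length must equal miRNA length")
        for i in range(L):
            cols.append(Column(pair_state(m[i], rev[i]), i + 1))
    elif gap[0] == "del":
        d = gap[1]
        if not 1 <= d <= L:
            raise ValueError("deletion position outside miRNA")
        if len(rev) != L - 1:
            raise ValueError("deleted site length must be miRNA length - 1")
        j = 0
        for i in range(L):
            if i + 1 == d:
                cols.append(Column(DEL_TARGET, i + 1))
            else:
                cols.append(Column(pair_state(m[i], rev[j]), i + 1))
                j += 1
    elif gap[0] == "ins":
        g = gap[1]
        if not 1 <= g <= L - 1:
            raise ValueError("insertion must fall between two miRNA positions")
        if len(rev) != L + 1:
            raise ValueError("inserted site length must be miRNA length + 1")
        for i in range(g):
            cols.append(Column(pair_state(m[i], rev[i]), i + 1))
        cols.append(Column(INS_TARGET, None, after_pos=g))
        for i in range(g, L):
            cols.append(Column(pair_state(m[i], rev[i + 1]), i + 1))
    else:
        raise ValueError(f"unknown gap kind {gap[0]!r}")
    return tuple(cols)


def _penalty_tables(scheme: ScoringScheme) -> tuple[np.ndarray, np.ndarray]:
    """(plain, seed) 4x4 penalty lookup tables indexed [mirna, target]."""
    plain = np.full((4, 4), scheme.noncanonical_penalty)
    for mcode in range(4):
        plain[mcode, _COMP_CODE[mcode]] = 0.0
    plain[_ENC["G"], _ENC["T"]] = scheme.wobble_penalty
    plain[_ENC["T"], _ENC["G"]] = scheme.wobble_penalty
    seed = plain.copy()
    seed[plain == scheme.noncanonical_penalty] += scheme.seed_extra_penalty
    return plain, seed


def _window_min(pos_pen: np.ndarray, bonds: Optional[np.ndarray],
                window: int) -> np.ndarray:
    """Min over sliding windows of ``window`` miRNA positions.

    ``pos_pen``: (n_offsets, L) per-position penalties; ``bonds``:
    (n_offsets, L-1) penalties charged between adjacent positions (target
    insertions), or None.
    """
    L = pos_pen.shape[1]
    if L <= window:
        total = pos_pen.sum(axis=1)
        if bonds is not None:
            total += bonds.sum(axis=1)
        return total
    cp = np.cumsum(pos_pen, axis=1)
    cp = np.concatenate([np.zeros((pos_pen.shape[0], 1)), cp], axis=1)
    wsum = cp[:, window:] - cp[:, :-window]  # (n, L-window+1)
    if bonds is not None:
        cb = np.cumsum(bonds, axis=1)
        cb = np.concatenate([np.zeros((bonds.shape[0], 1)), cb], axis=1)
        wsum = wsum + (cb[:, window - 1:] - cb[:, :L - window + 1])
    return wsum.min(axis=1)


def _candidate_scores(mir: np.ndarray, tx: np.ndarray, max_indels: int,
                      scheme: ScoringScheme
                      ) -> list[tuple[float, int, int, Optional[tuple[str, int]]]]:
    """Vectorized scores for all placements with at most one gap.

    Returns tuples ``(score, start, end, gap)``.
    """
    L = mir.size
    lo, hi = scheme.seed_range
    plain, seedtab = _penalty_tables(scheme)
    seed_mask = np.zeros(L, dtype=bool)
    seed_mask[lo - 1:hi] = True

    def pos_penalties(windows_rev: np.ndarray, mir_idx: np.ndarray) -> np.ndarray:
        # windows_rev: (n, k) reversed site windows; mir_idx: miRNA index per col
        pen = plain[mir[mir_idx][None, :], windows_rev]
        sm = seed_mask[mir_idx]
        if sm.any():
            pen[:, sm] = seedtab[mir[mir_idx[sm]][None, :], windows_rev[:, sm]]
        return pen

    out: list[tuple[float, int, int, Optional[tuple[str, int]]]] = []

    def sliding(width: int) -> np.ndarray:
        if tx.size < width:
            return np.empty((0, width), dtype=tx.dtype)
        return np.lib.stride_tricks.sliding_window_view(tx, width)[:, ::-1]

    # ungapped
    wrev = sliding(L)
    if wrev.shape[0]:
        pen = pos_penalties(wrev, np.arange(L))
        totals = _window_min(pen, None, scheme.window)
        out.extend((float(t), s, s + L, None) for s, t in enumerate(totals))

    if max_indels >= 1:
        # target deletion opposite miRNA position d
        wrev = sliding(L - 1)
        if wrev.shape[0]:
            for d in range(1, L + 1):
                mir_idx = np.array([i for i in range(L) if i + 1 != d])
                pen_cols = pos_penalties(wrev, mir_idx)
                pen = np.empty((wrev.shape[0], L))
                pen[:, [i for i in range(L) if i + 1 != d]] = pen_cols
                pen[:, d - 1] = scheme.indel_penalty
                totals = _window_min(pen, None, scheme.window)
                out.extend((float(t), s, s + L - 1, ("del", d))
                           for s, t in enumerate(totals))
        # target insertion between miRNA positions g and g+1
        wrev = sliding(L + 1)
        if wrev.shape[0]:
            for g in range(1, L):
                col_tgt = np.array(list(range(g)) + list(range(g + 1, L + 1)))
                pen = pos_penalties(wrev[:, col_tgt], np.arange(L))
                bonds = np.zeros((wrev.shape[0], L - 1))
                bonds[:, g - 1] = scheme.indel_penalty
                totals = _window_min(pen, bonds, scheme.window)
                out.extend((float(t), s, s + L + 1, ("ins", g))
                           for s, t in enumerate(totals))
    return out


def _two_gap_candidates(mirna: str, transcript: str, scheme: ScoringScheme
                        ) -> list[tuple[float, int, int, object]]:
    """Scalar enumeration of two-gap placements (max_indels == 2 only)."""
    from itertools import combinations

    m = normalize_seq(mirna)
    t = normalize_seq(transcript)
    L = len(m)
    out: list[tuple[float, int, int, object]] = []

    def eval_site(start: int, width: int, cols: tuple[Column, ...]) -> None:
        total, raw = window_total(cols, scheme)
        out.append((total, start, start + width, cols))

    # two deletions / two insertions / one of each
    for d1, d2 in combinations(range(1, L + 1), 2):
        width = L - 2
        for s in range(0, len(t) - width + 1):
            rev = t[s:s + width][::-1]
            cols, j = [], 0
            for i in range(L):
                if i + 1 in (d1, d2):
                    cols.append(Column(DEL_TARGET, i + 1))
                else:
                    cols.append(Column(pair_state(m[i], rev[j]), i + 1))
                    j += 1
            eval_site(s, width, tuple(cols))
    for g1, g2 in combinations(range(1, L), 2):
        width = L + 2
        for s in range(0, len(t) - width + 1):
            rev = t[s:s + width][::-1]
            cols, j = [], 0
            for i in range(L):
                if i == g1 or i == g2:  # insertion after miRNA position i
                    cols.append(Column(INS_TARGET, None, after_pos=i))
                    j += 1
                cols.append(Column(pair_state(m[i], rev[j]), i + 1))
                j += 1
            eval_site(s, width, tuple(cols))
    for d in range(1, L + 1):
        for g in range(1, L):
            width = L
            for s in range(0, len(t) - width + 1):
                rev = t[s:s + width][::-1]
                cols, j = [], 0
                for i in range(L):
                    if i == g:
                        cols.append(Column(INS_TARGET, None, after_pos=i))
                        j += 1
                    if i + 1 == d:
                        cols.append(Column(DEL_TARGET, i + 1))
                    else:
                        cols.append(Column(pair_state(m[i], rev[j]), i + 1))
                        j += 1
                eval_site(s, width, tuple(cols))
    return out


def select_nonoverlapping(candidates: Iterable[tuple[float, int, int]],
                          n_positions: int) -> list[int]:
    """Greedy best-first selection of non-overlapping spans.

    ``candidates`` yields (score, start, end); returns indices of the
    selected candidates in selection order.  Ties resolve leftmost.
    """
    cand = list(candidates)
    order = sorted(range(len(cand)),
                   key=lambda i: (cand[i][0], cand[i][1], cand[i][2]))
    occupied = np.zeros(n_positions, dtype=bool)
    chosen = []
    for i in order:
        _, s, e = cand[i][:3]
        if not occupied[s:e].any():
            occupied[s:e] = True
            chosen.append(i)
    return chosen


def align_duplex(mirna: str, transcript: str, max_indels: int = 1,
                 scheme: ScoringScheme = DEFAULT_SCHEME,
                 mirna_id: str = "mirna", transcript_id: str = "transcript"
                 ) -> list[DuplexAlignment]:
    """Best-scoring non-overlapping duplex placements of a miRNA on a transcript.

    Every offset is evaluated as an ungapped antiparallel duplex plus, up to
    ``max_indels``, gapped variants; overlapping placements are reduced to
    the best per overlap cluster (greedy best-first, leftmost on ties) and
    returned sorted by total score then site start.
    """
    if not 18 <= len(mirna) <= 26:
        raise ValueError("miRNA length must be 18-26 nt")
    if max_indels > 2:
        raise ValueError("max_indels must be <= 2")
    m = normalize_seq(mirna)
    t = normalize_seq(transcript)
    if len(t) < len(m):
        return []
    cand = _candidate_scores(encode(m), encode(t), min(max_indels, 1), scheme)
    two_gap = _two_gap_candidates(m, t, scheme) if max_indels >= 2 else []
    spans = [(sc, s, e) for sc, s, e, _ in cand]
    spans += [(sc, s, e) for sc, s, e, _ in two_gap]
    chosen = select_nonoverlapping(spans, len(t))
    alignments = []
    for i in chosen:
        if i < len(cand):
            score, s, e, gap = cand[i]
            cols = build_columns(m, t[s:e], gap)
        else:
            score, s, e, cols = two_gap[i - len(cand)]
        total, raw = window_total(cols, scheme)
        alignments.append(DuplexAlignment(mirna_id, transcript_id, s, e,
                                          tuple(cols), total, raw))
    alignments.sort(key=lambda a: (a.total_score, a.site_start, a.site_end))
    return alignments


def call_targets(mirnas: dict[str, str], transcripts: dict[str, str],
                 scheme: ScoringScheme = DEFAULT_SCHEME,
                 max_indels: int = 1) -> list[TargetHit]:
    """Score every miRNA against every transcript; accept scores < 3.0 (strict)."""
    if not mirnas or not transcripts:
        raise ValueError("mirnas and transcripts must be non-empty")
    hits = []
    for mid, mseq in mirnas.items():
        for tid, tseq in transcripts.items():
            for aln in align_duplex(mseq, tseq, max_indels, scheme, mid, tid):
                if aln.total_score < scheme.accept_below:
                    hits.append(TargetHit(aln, accepted=True))
    hits.sort(key=lambda h: (h.alignment.mirna_id, h.alignment.transcript_id,
                             h.alignment.total_score, h.alignment.site_start))
    return hits


def format_alignment(aln: DuplexAlignment, mirna: str, transcript: str) -> str:
    """Three-row text rendering: miRNA 3'->5' under target 5'->3'."""
    t = normalize_seq(transcript)[aln.site_start:aln.site_end]
    m = normalize_seq(mirna)
    # build column-wise strings; target row 5'->3', miRNA row reversed below
    tgt_row, sym_row, mir_row = [], [], []
    # columns are in miRNA 5'->3' order == target 3'->5'; render reversed
    t_idx = len(t)
    for col in aln.columns:
        if col.state == INS_TARGET:
            t_idx -= 1
            tgt_row.append(t[t_idx])
            sym_row.append(" ")
            mir_row.append("-")
        elif col.state == DEL_TARGET:
            tgt_row.append("-")
            sym_row.append(" ")
            mir_row.append(m[col.mirna_pos - 1])
        else:
            t_idx -= 1
            tgt_row.append(t[t_idx])
            sym_row.append("|" if col.state == WC else
                           "o" if col.state == GU else " ")
            mir_row.append(m[col.mirna_pos - 1])
    # rows were built miRNA 5'->3'; print target 5'->3' (reverse all)
    tgt = "".join(reversed(tgt_row)).replace("T", "U")
    sym = "".join(reversed(sym_row))
    mir = "".join(reversed(mir_row)).replace("T", "U")
    return (f"target 5' {tgt} 3'\n"
            f"          {sym}\n"
            f"miRNA  3' {mir} 5'")
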