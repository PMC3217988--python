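"""Raw small-RNA read cleanup: adapter clipping, filtering, tag collapsing.

Raw FASTQ reads are 3'-adapter read-through products of short inserts.
Each read is quality-filtered (mean Phred and no ambiguous bases), clipped
at the leftmost 3'-adapter occurrence, length-filtered (default 18-30 nt
kept), and the surviving inserts are collapsed into unique tags with
abundance counts — the atomic unit of all downstream analysis.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, TextIO, Union

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .target_score import normalize_seq

DEFAULT_MIN_LEN = 18  # keep inserts strictly longer than 17 nt
DEFAULT_MAX_LEN = 30
DEFAULT_MIN_MEAN_Q = 20.0
MIN_ADAPTER_OVERLAP = 6


@dataclass(frozen=True)
class SmallRNATag:
    """A collapsed unique read with its abundance count."""

    sequence: str  # DNA alphabet, U normalized to T
    count: int

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("tag count must be >= 1")
        if set(self.sequence) - set("ACGT"):
            raise ValueError("tag sequence must be over {A,C,G,T}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def rna(self) -> str:
        """Human-facing RNA-alphabet rendering."""
        return self.sequence.replace("T", "U")


@dataclass
class PreprocessStats:
    """Read accounting: every raw read lands in exactly one bucket."""

    n_raw: int = 0
    n_clean: int = 0
    n_adapter_only: int = 0
    n_low_quality: int = 0
    n_too_short: int = 0
    length_histogram: dict[int, int] = field(default_factory=dict)

    def check(self) -> None:
        if self.n_raw != (self.n_clean + self.n_adapter_only
                          + self.n_low_quality + self.n_too_short):
            raise AssertionError("preprocess buckets do not sum to raw reads")
        if sum(self.length_histogram.values()) != self.n_clean:
            raise AssertionError("length histogram does not sum to clean reads")


def clip_adapter(read: str, adapter3: str, max_mismatch: int = 0) -> str:
    """Return the insert preceding the leftmost 3'-adapter occurrence.

    An occurrence is a match of the adapter (or, at the read end, of an
    adapter prefix of at least 6 nt) with at most ``max_mismatch``
    mismatches over the overlapped region.  The whole read is returned
    when no occurrence is found.
    """
    if len(adapter3) < MIN_ADAPTER_OVERLAP:
        raise ValueError("adapter must be at least 6 nt")
    read = normalize_seq(read)
    adapter3 = normalize_seq(adapter3)
    n, a = len(read), len(adapter3)
    if max_mismatch == 0 and a <= n:
        # fast path: leftmost exact full-adapter hit
        pos = read.find(adapter3)
    else:
        pos = -1
        for i in range(0, n - a + 1):
            mm = 0
            for x, y in zip(read[i:i + a], adapter3):
                if x != y:
                    mm += 1
                    if mm > max_mismatch:
                        break
            else:
                pos = i
                break
    full_end = pos if pos >= 0 else n
    # suffix overlaps at the read end, left of any full hit
    for i in range(max(0, n - a + 1), full_end):
        ov = n - i
        if ov < MIN_ADAPTER_OVERLAP:
            break
        mm = sum(x != y for x, y in zip(read[i:], adapter3[:ov]))
        if mm <= max_mismatch:
            return read[:i]
    return read[:full_end]


def quality_filter(read: str, qual: str, min_mean_q: float = DEFAULT_MIN_MEAN_Q
                   ) -> bool:
    """Keep a read iff mean Phred >= threshold (inclusive) and no N base."""
    if len(read) != len(qual):
        raise ValueError("read and quality strings differ in length")
    if "N" in read.upper():
        return False
    if not qual:
        return False
    mean_q = sum(ord(c) - 33 for c in qual) / len(qual)
    return mean_q >= min_mean_q


def length_filter(insert: str, min_len: int = DEFAULT_MIN_LEN,
                  max_len: int = DEFAULT_MAX_LEN) -> bool:
    return min_len <= len(insert) <= max_len


def collapse(inserts: Iterable[str]) -> list[SmallRNATag]:
    """Collapse inserts to unique tags, descending count, ties lexicographic."""
    counts = Counter(normalize_seq(s) for s in inserts)
    return [SmallRNATag(seq, c)
            for seq, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))]


def length_distribution(tags: list[SmallRNATag]) -> pd.DataFrame:
    """Per-length unique/total counts and total percentages (histogram table)."""
    if not tags:
        raise ValueError("cannot summarize an empty tag set")
    rows: dict[int, list[int]] = {}
    for tag in tags:
        uniq, tot = rows.setdefault(tag.length, [0, 0])
        rows[tag.length] = [uniq + 1, tot + tag.count]
    total = sum(t for _, t in rows.values())
    df = pd.DataFrame(
        [(length, u, t, 100.0 * t / total)
         for length, (u, t) in sorted(rows.items())],
        columns=["length", "unique_count", "total_count", "total_percent"])
    return df


def run_preprocess(fastq: Union[str, TextIO], adapter3: str,
                   max_mismatch: int = 0,
                   min_mean_q: float = DEFAULT_MIN_MEAN_Q,
                   min_len: int = DEFAULT_MIN_LEN,
                   max_len: int = DEFAULT_MAX_LEN
                   ) -> tuple[list[SmallRNATag], PreprocessStats]:
    """Full clean-read pipeline: FASTQ -> collapsed, length-filtered tags.

    Order per read: quality filter, adapter clip, length filter.  Returns
    the collapsed tags and the per-bucket accounting.
    """
    stats = PreprocessStats()
    inserts: list[str] = []
    for _title, seq, qual in _iter_fastq(fastq):
        stats.n_raw += 1
        if not quality_filter(seq, qual, min_mean_q):
            stats.n_low_quality += 1
            continue
        insert = clip_adapter(seq, adapter3, max_mismatch)
        if len(insert) == 0:
            stats.n_adapter_only += 1
            continue
        if not length_filter(insert, min_len, max_len):
            stats.n_too_short += 1
            continue
        stats.n_clean += 1
        stats.length_histogram[len(insert)] = \
            stats.length_histogram.get(len(insert), 0) + 1
        inserts.append(insert)
    stats.check()
    return collapse(inserts), stats


def _iter_fastq(fastq: Union[str, TextIO]) -> Iterator[tuple[str, str, str]]:
    if isinstance(fastq, str):
        with open(fastq) as fh:
            yield from FastqGeneralIterator(fh)
    else:
        yield from FastqGeneralIterator(fastq)


def write_tags_fasta(tags: list[SmallRNATag], path: str) -> None:
    """Collapsed tags as FASTA with headers ``>tag<rank>_x<count>``."""
    with open(path, "w") as fh:
        for rank, tag in enumerate(tags, 1):
            fh.write(f">tag{rank}_x{tag.count}\n{tag.sequence}\n")


def read_tags_fasta(path: str) -> list[SmallRNATag]:
    tags = []
    with open(path) as fh:
        header = None
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                header = line[1:]
            elif line:
                count = int(header.rsplit("_x", 1)[1]) if header and "_x" in header else 1
                tags.append(SmallRNATag(normalize_seq(line), count))
    return tags


def write_stats(stats: PreprocessStats, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("metric\tvalue\n")
        for k in ("n_raw", "n_clean", "n_adapter_only",
                  "n_low_quality", "n_too_short"):
            fh.write(f"{k}\t{getattr(stats, k)}\n")
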