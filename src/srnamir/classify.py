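"""Tag classification by perfect matching against reference RNA classes.

Each collapsed tag is assigned to exactly one category — known miRNA,
rRNA, tRNA, snRNA, snoRNA, siRNA, or unannotated — by exact full-sequence
matching against per-class reference sets, resolving multi-class matches
by a configurable priority order (miRNA first by default).  Matching is
orientation-aware: the tag as sequenced against sense-strand references,
with no mismatches tolerated.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .preprocess import SmallRNATag
from .target_score import normalize_seq

DEFAULT_PRIORITY = ("miRNA", "rRNA", "tRNA", "snRNA", "snoRNA", "siRNA")
UNANNOTATED = "unannotated"

_FAMILY_RE = re.compile(r"(?:^|-)mir(\d+)", re.IGNORECASE)


@dataclass(frozen=True)
class KnownMirnaHit:
    """A tag exactly matching a reference mature miRNA."""

    tag: SmallRNATag
    mirna_id: str
    family: str


class ReferenceIndex:
    """Exact-match index: sequence -> sorted reference ids."""

    def __init__(self, sequences: dict[str, str]):
        self._by_seq: dict[str, list[str]] = {}
        for rid, seq in sequences.items():
            self._by_seq.setdefault(normalize_seq(seq), []).append(rid)
        for ids in self._by_seq.values():
            ids.sort()

    def lookup(self, sequence: str) -> list[str]:
        return list(self._by_seq.get(normalize_seq(sequence), ()))


def match_reference(tag: SmallRNATag, index: ReferenceIndex) -> list[str]:
    """Ids of reference entries whose sequence equals the tag exactly."""
    return index.lookup(tag.sequence)


def family_name(mirna_id: str) -> str:
    """Normalize a mature miRNA id to its family (ahy-miR156f -> miR156)."""
    m = _FAMILY_RE.search(mirna_id)
    if not m:
        return mirna_id
    return f"miR{m.group(1)}"


def categorize(tags: Sequence[SmallRNATag],
               references: dict[str, dict[str, str]],
               priority: Sequence[str] = DEFAULT_PRIORITY
               ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Label every tag and build the per-category summary table.

    Parameters
    ----------
    tags
        Collapsed tags.
    references
        Mapping class name -> {reference id -> sequence}.
    priority
        Class resolution order; a tag gets the first class with a perfect
        match, otherwise "unannotated".

    Returns
    -------
    (per_tag, summary)
        ``per_tag``: tag, count, label, hit_id.  ``summary``: the category
        table with unique/total counts and percentages; its first row is
        the all-tags total at 100%.
    """
    unknown = [c for c in priority if c not in references]
    if unknown:
        raise ValueError(f"priority classes missing from references: {unknown}")
    indexes = {cls: ReferenceIndex(seqs) for cls, seqs in references.items()}
    records = []
    for tag in tags:
        label, hit_id = UNANNOTATED, ""
        for cls in priority:
            ids = indexes[cls].lookup(tag.sequence)
            if ids:
                label, hit_id = cls, ";".join(ids)
                break
        records.append((tag.sequence, tag.count, label, hit_id))
    per_tag = pd.DataFrame(records,
                           columns=["sequence", "count", "label", "hit_id"])
    summary = category_summary(per_tag, priority)
    return per_tag, summary


def category_summary(per_tag: pd.DataFrame,
                     priority: Sequence[str] = DEFAULT_PRIORITY) -> pd.DataFrame:
    """Unique/total counts and percentages per category (Total row first)."""
    total_unique = len(per_tag)
    total_reads = int(per_tag["count"].sum())
    rows = [("Total small RNAs", total_unique, 100.0, total_reads, 100.0)]
    for cls in list(priority) + [UNANNOTATED]:
        sub = per_tag[per_tag["label"] == cls]
        uniq = len(sub)
        tot = int(sub["count"].sum())
        rows.append((cls,
                     uniq, 100.0 * uniq / total_unique if total_unique else 0.0,
                     tot, 100.0 * tot / total_reads if total_reads else 0.0))
    return pd.DataFrame(rows, columns=["category", "unique_count",
                                       "unique_percent", "total_count",
                                       "total_percent"])


def known_mirna_hits(per_tag: pd.DataFrame,
                     mirna_refs: dict[str, str]) -> list[KnownMirnaHit]:
    index = ReferenceIndex(mirna_refs)
    hits = []
    for _, row in per_tag[per_tag["label"] == "miRNA"].iterrows():
        tag = SmallRNATag(row["sequence"], int(row["count"]))
        for rid in index.lookup(tag.sequence):
            hits.append(KnownMirnaHit(tag, rid, family_name(rid)))
    return hits


def family_abundance(hits: Sequence[KnownMirnaHit]) -> pd.DataFrame:
    """Per-family member counts and summed read abundance.

    ``member_count`` counts distinct mature ids matched; ``total_reads``
    sums tag counts over the family (a tag matching several members of one
    family is counted once toward total_reads).
    """
    members: dict[str, set[str]] = {}
    reads: dict[str, dict[str, int]] = {}
    for hit in hits:
        members.setdefault(hit.family, set()).add(hit.mirna_id)
        reads.setdefault(hit.family, {})[hit.tag.sequence] = hit.tag.count
    df = pd.DataFrame(
        [(fam, len(members[fam]), sum(reads[fam].values()))
         for fam in members],
        columns=["family", "member_count", "total_reads"])
    return df.sort_values(["total_reads", "family"],
                          ascending=[False, True]).reset_index(drop=True)
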