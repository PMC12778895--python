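"""Adaptor trimming, length filtering, and hierarchical category-ordered
mapping of footprint reads onto the transcript references.

Reads are assigned to the FIRST category (rRNA, tRNA, snRNA, snoRNA,
miRNA, lncRNA, mRNA) in which they have a coding-strand hit with at most
one mismatch; within a category a 0-mismatch hit beats a 1-mismatch hit,
then the lexicographically smallest transcript id, then the leftmost start.
Reverse-strand hits are never reported. This is an exact/1-mismatch
substring search over an in-memory index sized for desk-scale references,
not a re-implementation of a short-read aligner.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import ReferenceSet

logger = logging.getLogger(__name__)

DEFAULT_ADAPTOR = "CTGTAGGCACCATCAAT"
DEFAULT_MIN_LEN = 18
#: minimum 3'-end suffix overlap with the adaptor prefix to trim
MIN_ADAPTOR_OVERLAP = 3


def trim_read(
    seq: str,
    adaptor: str = DEFAULT_ADAPTOR,
    min_len: int = DEFAULT_MIN_LEN,
    min_overlap: int = MIN_ADAPTOR_OVERLAP,
) -> str | None:
    """Trim the adaptor off a read's 3' end; ``None`` means discarded.

    The read is truncated at the leftmost full occurrence of the adaptor;
    failing that, at the longest read suffix that equals an adaptor prefix
    of at least ``min_overlap`` nt. Reads without any adaptor trace are
    kept whole. Post-trim sequences shorter than ``min_len`` are discarded.
    """
    if not seq:
        raise ValueError("empty read")
    pos = seq.find(adaptor)
    if pos != -1:
        trimmed = seq[:pos]
    else:
        trimmed = seq
        max_k = min(len(adaptor) - 1, len(seq))
        for k in range(max_k, min_overlap - 1, -1):
            if seq.endswith(adaptor[:k]):
                trimmed = seq[: len(seq) - k]
                break
    return trimmed if len(trimmed) >= min_len else None


@dataclass(frozen=True)
class AlignedFootprint:
    """A mapped footprint: category, transcript, 0-based 5' start, length."""

    read_id: str
    category: str
    transcript_id: str
    start: int
    length: int
    mismatches: int


_BASE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


class _CategoryIndex:
    """Concatenated transcript sequences of one category, in sorted-id order
    (so that scan position order equals the documented tie-break order)."""

    def __init__(self, transcripts):
        self.tids = [t.transcript_id for t in transcripts]
        self.starts = []
        self.ends = []
        parts = []
        pos = 0
        for t in transcripts:
            self.starts.append(pos)
            parts.append(t.sequence)
            pos += t.length
            self.ends.append(pos)
            parts.append("N")  # separator never matched by ACGT reads
            pos += 1
        self.concat = "".join(parts)
        self.u8 = np.frombuffer(self.concat.encode(), dtype=np.uint8)
        self.starts = np.array(self.starts)
        self.ends = np.array(self.ends)

    def _locate(self, pos: int, length: int) -> tuple[str, int] | None:
        i = int(np.searchsorted(self.starts, pos, side="right")) - 1
        if i < 0 or pos + length > self.ends[i]:
            return None
        return self.tids[i], pos - int(self.starts[i])

    def exact(self, seq: str) -> tuple[str, int] | None:
        pos = self.concat.find(seq)
        while pos != -1:
            hit = self._locate(pos, len(seq))
            if hit is not None:
                return hit
            pos = self.concat.find(seq, pos + 1)
        return None

    def one_mismatch(self, seq: str) -> tuple[str, int] | None:
        L = len(seq)
        if len(self.u8) < L:
            return None
        q = np.frombuffer(seq.encode(), dtype=np.uint8)
        windows = np.lib.stride_tricks.sliding_window_view(self.u8, L)
        mism = (windows != q).sum(axis=1)
        for pos in np.flatnonzero(mism == 1):
            hit = self._locate(int(pos), L)
            if hit is not None:
                return hit
        return None


def hierarchical_map(
    reads, ref: ReferenceSet
) -> tuple[list[AlignedFootprint], pd.DataFrame, list[str]]:
    """Map trimmed reads to the reference hierarchy.

    ``reads`` is an iterable of ``(read_id, sequence)``. Returns the
    assigned footprints, a per-category tally (count + percent, including
    unmapped), and the unmapped read ids. Every read lands in exactly one
    category or in the unmapped set.
    """
    indexes: dict[str, _CategoryIndex] = {}
    for cat in ref.category_order:
        txs = ref.by_category(cat)
        if not txs:
            logger.warning("reference category %s is empty; skipped", cat)
            continue
        indexes[cat] = _CategoryIndex(txs)

    footprints: list[AlignedFootprint] = []
    unmapped: list[str] = []
    tally = {cat: 0 for cat in indexes}
    for read_id, seq in reads:
        seq = seq.upper()
        hit = None
        for cat, index in indexes.items():
            exact = index.exact(seq)
            if exact is not None:
                hit = (cat, exact[0], exact[1], 0)
                break
            near = index.one_mismatch(seq)
            if near is not None:
                hit = (cat, near[0], near[1], 1)
                break
        if hit is None:
            unmapped.append(read_id)
        else:
            cat, tid, start, mism = hit
            tally[cat] += 1
            footprints.append(
                AlignedFootprint(
                    read_id=read_id, category=cat, transcript_id=tid,
                    start=start, length=len(seq), mismatches=mism,
                )
            )

    total = len(footprints) + len(unmapped)
    rows = [
        {"category": cat, "count": n, "percent": 100.0 * n / total if total else 0.0}
        for cat, n in tally.items()
    ]
    rows.append(
        {"category": "unmapped", "count": len(unmapped),
         "percent": 100.0 * len(unmapped) / total if total else 0.0}
    )
    return footprints, pd.DataFrame(rows), unmapped


def footprints_to_frame(footprints: list[AlignedFootprint]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"read_id": f.read_id, "category": f.category,
             "transcript_id": f.transcript_id, "start": f.start,
             "length": f.length, "mismatches": f.mismatches}
            for f in footprints
        ],
        columns=["read_id", "category", "transcript_id", "start", "length", "mismatches"],
    )
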