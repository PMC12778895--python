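"""P-site offset calibration, P-site assignment, metagene profiles, and
frame statistics.

The P site holds the peptidyl-tRNA; during initiation it covers the start
codon, so footprints over annotated starts calibrate the per-length offset
from a footprint's 5' end to its P site. Offsets are estimated as the mode
of ``cds_start - five_prime_end`` over start-covering reads, restricted to
the biologically plausible 10-14 nt range, with ties broken toward the
smaller offset.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import ReferenceSet
from .mapping import AlignedFootprint

OFFSET_RANGE = (10, 14)
MIN_SUPPORT = 50

START_WINDOW = (-48, 33)
STOP_WINDOW = (-33, 48)


@dataclass
class OffsetTable:
    """Per-read-length 5'-end-to-P-site offsets with their read support."""

    offsets: dict[int, int]
    support: dict[int, int]

    def __getitem__(self, length: int) -> int:
        return self.offsets[length]

    def __contains__(self, length: int) -> bool:
        return length in self.offsets

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"length": sorted(self.offsets),
             "offset": [self.offsets[L] for L in sorted(self.offsets)],
             "support": [self.support[L] for L in sorted(self.offsets)]}
        )


def estimate_offsets(
    footprints: list[AlignedFootprint],
    ref: ReferenceSet,
    min_support: int = MIN_SUPPORT,
    offset_range: tuple[int, int] = OFFSET_RANGE,
) -> OffsetTable:
    """Calibrate per-length P-site offsets from start-codon-covering reads.

    For each length the offset is the modal value of
    ``cds_start - five_prime_end`` among mRNA reads whose span covers a
    start codon, restricted to ``offset_range``; ties break toward the
    smaller offset. Lengths with fewer than ``min_support`` usable reads
    are excluded with a warning.
    """
    lo, hi = offset_range
    counters: dict[int, Counter] = {}
    for f in footprints:
        if f.category != "mRNA":
            continue
        t = ref[f.transcript_id]
        if not (f.start <= t.cds_start < f.start + f.length):
            continue
        cand = t.cds_start - f.start
        if lo <= cand <= hi:
            counters.setdefault(f.length, Counter())[cand] += 1

    offsets: dict[int, int] = {}
    support: dict[int, int] = {}
    for length, counter in sorted(counters.items()):
        n = sum(counter.values())
        if n < min_support:
            warnings.warn(
                f"length {length}: only {n} start-covering reads"
                f" (< {min_support}); excluded from offset table",
                stacklevel=2,
            )
            continue
        best = max(counter.values())
        offsets[length] = min(o for o, c in counter.items() if c == best)
        support[length] = n
    return OffsetTable(offsets=offsets, support=support)


@dataclass(frozen=True)
class PsiteRecord:
    """One inferred P site: transcript coordinate, frame and region
    (frame/region are None outside mRNA)."""

    read_id: str
    transcript_id: str
    psite: int
    length: int
    frame: int | None
    region: str | None


def assign_psites(
    footprints: list[AlignedFootprint],
    offsets: OffsetTable,
    ref: ReferenceSet,
) -> tuple[list[PsiteRecord], dict[str, int]]:
    """P site = 5' start + offset[length]; annotate frame and region.

    Reads whose length is absent from the offset table are skipped and
    counted; records whose P site falls outside the transcript are dropped
    and counted.
    """
    records: list[PsiteRecord] = []
    stats = {"skipped_no_offset": 0, "dropped_out_of_bounds": 0}
    for f in footprints:
        if f.length not in offsets:
            stats["skipped_no_offset"] += 1
            continue
        psite = f.start + offsets[f.length]
        t = ref[f.transcript_id]
        if not 0 <= psite < t.length:
            stats["dropped_out_of_bounds"] += 1
            continue
        if t.is_mrna:
            frame = (psite - t.cds_start) % 3
            region = t.region_of(psite)
        else:
            frame = region = None
        records.append(
            PsiteRecord(
                read_id=f.read_id, transcript_id=f.transcript_id,
                psite=psite, length=f.length, frame=frame, region=region,
            )
        )
    return records, stats


def psites_to_frame(records: list[PsiteRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"read_id": r.read_id, "transcript_id": r.transcript_id,
             "psite": r.psite, "length": r.length,
             "frame": -1 if r.frame is None else r.frame,
             "region": r.region or "nc"}
            for r in records
        ],
        columns=["read_id", "transcript_id", "psite", "length", "frame", "region"],
    )


@dataclass
class MetageneProfile:
    """Per-position event counts around a start/stop anchor.

    ``counts`` is indexed by signed distance from the first nucleotide of
    the anchor codon, with one column per read length plus ``all``;
    ``fraction`` is the combined column normalized to sum to 1.
    """

    anchor: str
    mode: str
    window: tuple[int, int]
    counts: pd.DataFrame
    fraction: pd.Series = field(init=False)

    def __post_init__(self) -> None:
        total = self.counts["all"].sum()
        self.fraction = (
            self.counts["all"] / total if total > 0 else self.counts["all"] * 0.0
        )

    def argmax(self, length: int | None = None) -> int:
        col = "all" if length is None else length
        return int(self.counts[col].idxmax())


def metagene(
    events,
    ref: ReferenceSet,
    anchor: str = "start",
    mode: str = "p5",
    window: tuple[int, int] | None = None,
) -> MetageneProfile:
    """Aggregate footprint 5' ends, 3' ends, or P sites around start/stop
    codons.

    ``events`` are AlignedFootprints for modes ``p5``/``p3`` and
    PsiteRecords for mode ``psite``. Distance 0 is the first nucleotide of
    the start codon (anchor="start") or of the stop codon (anchor="stop").
    Only mRNA events contribute; events outside the window are ignored.
    """
    if anchor not in ("start", "stop"):
        raise ValueError("anchor must be 'start' or 'stop'")
    if mode not in ("p5", "p3", "psite"):
        raise ValueError("mode must be 'p5', 'p3' or 'psite'")
    if window is None:
        window = START_WINDOW if anchor == "start" else STOP_WINDOW
    lo, hi = window
    positions = np.arange(lo, hi + 1)

    per_length: dict[int, np.ndarray] = {}
    for ev in events:
        if mode == "psite":
            if ev.region is None:
                continue
            tid, pos, length = ev.transcript_id, ev.psite, ev.length
        else:
            if ev.category != "mRNA":
                continue
            tid, length = ev.transcript_id, ev.length
            pos = ev.start if mode == "p5" else ev.start + ev.length - 1
        t = ref[tid]
        anchor_pos = t.cds_start if anchor == "start" else t.cds_end - 3
        d = pos - anchor_pos
        if lo <= d <= hi:
            if length not in per_length:
                per_length[length] = np.zeros(len(positions), dtype=int)
            per_length[length][d - lo] += 1

    counts = pd.DataFrame(
        {L: per_length[L] for L in sorted(per_length)}, index=positions
    )
    counts["all"] = counts.sum(axis=1) if len(counts.columns) else 0
    counts.index.name = "position"
    return MetageneProfile(anchor=anchor, mode=mode, window=window, counts=counts)


def frame_stats(records: list[PsiteRecord]) -> tuple[pd.Series, pd.Series]:
    """CDS frame fractions and per-length read shares.

    Frame fractions are computed over CDS-region P sites only and sum to 1;
    length shares are computed over all records passed in.
    """
    cds_frames = [r.frame for r in records if r.region == "cds"]
    if not cds_frames:
        raise ValueError("no CDS P-site records")
    frame_counts = pd.Series(cds_frames).value_counts().reindex([0, 1, 2], fill_value=0)
    frames = frame_counts / frame_counts.sum()
    frames.index.name = "frame"
    lengths = pd.Series([r.length for r in records]).value_counts(normalize=True).sort_index()
    lengths.index.name = "length"
    return frames, lengths
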