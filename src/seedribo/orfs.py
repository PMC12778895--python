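"""ORF/uORF prediction, uORF-vs-mORF shift detection, lncRNA translation
calls, and peptide-evidence matching.

An ORF runs from an AUG through the last nucleotide of the first in-frame
stop codon; its length in bp therefore includes the stop codon, and the
"longer than 60 bp" retention rule is a strict inequality (a 63-bp ORF,
i.e. 20 encoded amino acids, is the shortest kept at the default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .annotation import ReferenceSet
from .difftrans import CountMatrix, bh_adjust, pairwise_de, rpkm, size_factors

START = "ATG"
STOPS = ("TAA", "TAG", "TGA")

DEFAULT_MIN_ORF_BP = 60
DEFAULT_RPKM_MIN = 5.0


@dataclass(frozen=True)
class OrfRecord:
    """One predicted ORF on a host transcript (0-based half-open coords)."""

    host_id: str
    start: int
    end: int  # one past the last nucleotide of the stop codon
    frame: int  # start % 3 within the scanned sequence
    peptide: str  # encoded peptide, stop symbol excluded

    @property
    def length_bp(self) -> int:
        return self.end - self.start


def predict_orfs(
    sequence: str,
    min_len_bp: int = DEFAULT_MIN_ORF_BP,
    host_id: str = "",
    offset: int = 0,
) -> list[OrfRecord]:
    """All AUG-initiated ORFs with an in-frame stop inside ``sequence``.

    Every qualifying AUG yields its own record (no longest-only collapsing;
    nested and overlapping ORFs are all reported). Kept iff
    ``length_bp > min_len_bp``; AUGs without an in-frame downstream stop
    are discarded. ``offset`` shifts reported coordinates onto the host
    transcript when ``sequence`` is a subsequence.
    """
    seq = sequence.upper().replace("U", "T")
    n = len(seq)
    out: list[OrfRecord] = []
    pos = seq.find(START)
    while pos != -1:
        for stop_at in range(pos + 3, n - 2, 3):
            codon = seq[stop_at : stop_at + 3]
            if codon in STOPS:
                length = stop_at + 3 - pos
                if length > min_len_bp:
                    peptide = str(Seq(seq[pos:stop_at]).translate())
                    out.append(
                        OrfRecord(
                            host_id=host_id,
                            start=pos + offset,
                            end=stop_at + 3 + offset,
                            frame=pos % 3,
                            peptide=peptide,
                        )
                    )
                break
        pos = seq.find(START, pos + 1)
    return out


def annotate_uorfs(
    ref: ReferenceSet, min_len_bp: int = DEFAULT_MIN_ORF_BP
) -> pd.DataFrame:
    """Predict uORFs in every mRNA 5' UTR.

    The scan is restricted to the UTR subsequence, so ORFs whose stop would
    fall at or beyond the annotated CDS start are never reported. Returns a
    frame with one row per uORF: feature_id, transcript_id, gene_id, start,
    end (transcript coordinates), length_bp, frame, peptide.
    """
    rows = []
    for t in ref.mrnas():
        if t.utr5_len == 0:
            continue
        utr = t.sequence[: t.cds_start]
        for i, orf in enumerate(predict_orfs(utr, min_len_bp, host_id=t.transcript_id)):
            rows.append(
                {
                    "feature_id": f"{t.transcript_id}.uORF{i + 1}",
                    "transcript_id": t.transcript_id,
                    "gene_id": t.gene_id,
                    "start": orf.start,
                    "end": orf.end,
                    "length_bp": orf.length_bp,
                    "frame": orf.frame,
                    "peptide": orf.peptide,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "feature_id", "transcript_id", "gene_id",
            "start", "end", "length_bp", "frame", "peptide",
        ],
    )


def uorfs_to_gff(uorfs: pd.DataFrame) -> str:
    """uORF annotation as GFF3 (1-based closed) on transcript coordinates."""
    lines = ["##gff-version 3"]
    for row in uorfs.itertuples():
        lines.append(
            f"{row.transcript_id}\tseedribo\tuORF\t{row.start + 1}\t{row.end}"
            f"\t.\t+\t0\tID={row.feature_id};gene_id={row.gene_id}"
        )
    return "\n".join(lines) + "\n"


def parse_uorf_gff(gff_text: str) -> pd.DataFrame:
    rows = []
    for line in gff_text.splitlines():
        if not line or line.startswith("#"):
            continue
        seqid, _, ftype, start, end, _, _, _, attrs = line.split("\t")
        if ftype != "uORF":
            continue
        attr = dict(kv.split("=", 1) for kv in attrs.split(";"))
        rows.append(
            {
                "feature_id": attr["ID"],
                "transcript_id": seqid,
                "gene_id": attr.get("gene_id", seqid),
                "start": int(start) - 1,
                "end": int(end),
            }
        )
    return pd.DataFrame(rows)


def count_features(psite_records, features: pd.DataFrame) -> pd.Series:
    """Count P sites falling inside feature intervals.

    ``features`` needs columns feature_id, transcript_id, start, end
    (half-open, transcript coordinates). Features of one class are assumed
    non-overlapping; a P site increments the single feature containing it.
    """
    by_transcript: dict[str, list[tuple[int, int, str]]] = {}
    for row in features.itertuples():
        by_transcript.setdefault(row.transcript_id, []).append(
            (row.start, row.end, row.feature_id)
        )
    counts = {fid: 0 for fid in features["feature_id"]}
    for rec in psite_records:
        for start, end, fid in by_transcript.get(rec.transcript_id, ()):
            if start <= rec.psite < end:
                counts[fid] += 1
                break
    return pd.Series(counts, name="count", dtype=int)


def _passes_rpkm_filter(
    counts: CountMatrix,
    lengths: pd.Series,
    stages: tuple[str, str],
    rpkm_min: float,
) -> pd.Series:
    """Boolean per feature: rpkm > rpkm_min in every replicate of both stages."""
    sub = counts.subset(stages=stages)
    try:
        sf = size_factors(sub.counts)
    except Exception:
        # sparse toy matrices may lack an all-nonzero feature; the filter
        # then falls back to library-size factors
        totals = sub.counts.sum(axis=0).astype(float)
        sf = totals / totals.mean() if totals.mean() > 0 else totals + 1.0
    normed = sub.counts / sf
    vals = rpkm(normed, lengths.reindex(sub.counts.index))
    return (vals > rpkm_min).all(axis=1)


def uorf_morf_shift(
    uorf_counts: CountMatrix,
    cds_counts: CountMatrix,
    stages: tuple[str, str],
    uorf_lengths: pd.Series,
    cds_lengths: pd.Series,
    uorf_to_gene: pd.Series,
    rpkm_min: float = DEFAULT_RPKM_MIN,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Detect genes whose uORF and CDS footprint counts shift in opposite
    directions between two consecutive stages.

    Genes are kept only when both the uORF and the CDS exceed the rpkm
    threshold in every replicate of both stages. Each region is tested with
    a negative-binomial Wald contrast between the stages; BH adjustment is
    applied per region across the retained genes. A gene is flagged
    ``opposite`` iff both adjusted p-values are below ``alpha`` and the two
    log2 fold changes have strictly opposite signs.
    """
    keep_u = _passes_rpkm_filter(uorf_counts, uorf_lengths, stages, rpkm_min)
    keep_c = _passes_rpkm_filter(cds_counts, cds_lengths, stages, rpkm_min)
    gene_of_uorf = uorf_to_gene.reindex(keep_u.index)
    genes_u = set(gene_of_uorf[keep_u.values])
    genes_c = set(keep_c.index[keep_c.values])
    genes = sorted(genes_u & genes_c)
    if not genes:
        return pd.DataFrame(
            columns=[
                "gene_id", "log2FC_uorf", "p_uorf", "padj_uorf",
                "log2FC_cds", "p_cds", "padj_cds", "opposite",
            ]
        ).set_index("gene_id")

    uorf_ids = [
        uid for uid in uorf_counts.counts.index
        if keep_u.get(uid, False) and gene_of_uorf.get(uid) in genes
    ]
    # one uORF per gene enters the test; with several, the longest wins
    best_uorf: dict[str, str] = {}
    for uid in uorf_ids:
        g = gene_of_uorf[uid]
        if g not in best_uorf or uorf_lengths[uid] > uorf_lengths[best_uorf[g]]:
            best_uorf[g] = uid

    de_u = pairwise_de(
        uorf_counts.subset(features=list(best_uorf.values())), stages
    )
    de_c = pairwise_de(cds_counts.subset(features=genes), stages)

    rows = []
    for g in genes:
        uid = best_uorf[g]
        if uid not in de_u.index or g not in de_c.index:
            continue
        lu, pu = de_u.loc[uid, "log2FC"], de_u.loc[uid, "p"]
        lc, pc = de_c.loc[g, "log2FC"], de_c.loc[g, "p"]
        rows.append({"gene_id": g, "log2FC_uorf": lu, "p_uorf": pu,
                     "log2FC_cds": lc, "p_cds": pc})
    res = pd.DataFrame(rows).set_index("gene_id")
    res["padj_uorf"] = bh_adjust(res["p_uorf"])
    res["padj_cds"] = bh_adjust(res["p_cds"])
    res["opposite"] = (
        (res["padj_uorf"] < alpha)
        & (res["padj_cds"] < alpha)
        & (np.sign(res["log2FC_uorf"]) == -np.sign(res["log2FC_cds"]))
        & (res["log2FC_uorf"] != 0)
    )
    return res


def lncrna_translation(
    ribo: CountMatrix,
    total: CountMatrix,
    stages: tuple[str, str],
    lncrna_lengths: pd.Series,
    orf_bearing: set[str] | None = None,
    rpkm_min: float = DEFAULT_RPKM_MIN,
) -> pd.DataFrame:
    """Translationally regulated lncRNAs between two stages.

    lncRNAs must pass the rpkm filter in every replicate of both assays;
    survivors are then tested for a translation-efficiency change with the
    interaction LRT. ``regulated`` follows the standard significance rule
    (padj < 0.05 and at least two-fold TE change); ``has_orf`` marks the
    ORF-bearing subset when ``orf_bearing`` ids are given.
    """
    from .difftrans import te_lrt

    lnc_ids = [i for i in lncrna_lengths.index if i in ribo.counts.index]
    ribo_l = ribo.subset(features=lnc_ids)
    total_l = total.subset(features=lnc_ids)
    keep = (
        _passes_rpkm_filter(ribo_l, lncrna_lengths, stages, rpkm_min)
        & _passes_rpkm_filter(total_l, lncrna_lengths, stages, rpkm_min)
    )
    kept = sorted(keep.index[keep.values])
    if not kept:
        return pd.DataFrame(
            columns=["baseMean", "log2FC", "stat", "p", "padj",
                     "significant", "regulated", "has_orf"]
        )
    res = te_lrt(ribo_l.subset(features=kept), total_l.subset(features=kept), stages)
    res = res.rename(columns={})
    res["regulated"] = res["significant"]
    res["has_orf"] = [
        (orf_bearing is not None and fid in orf_bearing) for fid in res.index
    ]
    return res


def match_peptides(
    predicted: pd.Series, observed: pd.DataFrame, min_obs_len: int = 7
) -> pd.DataFrame:
    """Exact-containment matching of observed peptides against predicted
    ORF peptides.

    ``predicted`` maps orf/feature id -> peptide string; ``observed`` needs
    columns ``peptide`` and optionally ``stage``. A match requires the
    observed peptide to be an exact substring (I and L distinct); one row
    per (observed peptide, predicted ORF) pair is returned.
    """
    rows = []
    for obs in observed.itertuples():
        pep = obs.peptide
        if len(pep) < min_obs_len:
            continue
        stage = getattr(obs, "stage", "")
        for orf_id, pred in predicted.items():
            if pep in pred:
                rows.append({"peptide": pep, "orf_id": orf_id, "stage": stage})
    return pd.DataFrame(rows, columns=["peptide", "orf_id", "stage"])
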