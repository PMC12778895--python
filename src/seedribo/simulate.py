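"""Synthetic references, ribosome footprints, and count matrices with the
statistical structure the downstream analysis assumes.

The five stage presets correspond to the germination time course (dry
seeds, then 6/26/48/72 hours after imbibition). Each preset fixes the
footprint length mixture over 27/28/29 nt, the per-length 5'-end-to-P-site
offsets, the frame-error rate, the UTR5/CDS/UTR3 read shares, the relative
start-codon stalling weight, codon-specific pause weights (glycine,
aspartate, tyrosine and proline codons elevated, stage-dependent), the
stop-codon geometry (a pause 4 nt upstream of the stop and a fraction of
+1-shifted footprints), and the contaminant read mixture. Every read's true
source, P site, length, frame and region are recorded in a truth table.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .annotation import ReferenceSet, TranscriptModel
from .difftrans import CountMatrix, DesignError

ADAPTOR = "CTGTAGGCACCATCAAT"

STAGES = ("dry", "hai6", "hai26", "hai48", "hai72")

_ALL_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
_STOP_CODONS = ("TAA", "TAG", "TGA")
_NONSTOP_CODONS = [c for c in _ALL_CODONS if c not in _STOP_CODONS]
_CODON_TO_AA = {c: str(Seq(c).translate()) for c in _ALL_CODONS}


def codon_weights(
    aa_weights: dict[str, float], stop_weights: dict[str, float] | float = 0.05
) -> dict[str, float]:
    """Expand amino-acid-level pause weights to per-codon weights."""
    out = {}
    for codon, aa in _CODON_TO_AA.items():
        if codon in _STOP_CODONS:
            if isinstance(stop_weights, dict):
                out[codon] = stop_weights.get(codon, 0.05)
            else:
                out[codon] = float(stop_weights)
        else:
            out[codon] = aa_weights.get(aa, 1.0)
    return out


@dataclass(frozen=True)
class StagePreset:
    """All generative parameters of one physiological stage."""

    name: str
    length_probs: dict[int, float]
    p_offset_by_length: dict[int, int]
    frame_error: float
    region_weights: tuple[float, float, float]  # (utr5, cds, utr3)
    start_pause_weight: float
    codon_pause_weights: dict[str, float]
    stop_minus4_weight: float
    plus1_stop_fraction: float
    contaminant_fracs: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if abs(sum(self.length_probs.values()) - 1.0) > 1e-9:
            raise ValueError("length_probs must sum to 1")
        if abs(sum(self.region_weights) - 1.0) > 1e-9:
            raise ValueError("region_weights must sum to 1")
        if not 0 <= self.frame_error <= 1 or not 0 <= self.plus1_stop_fraction <= 1:
            raise ValueError("probabilities must lie in [0, 1]")
        for length, off in self.p_offset_by_length.items():
            if not 10 <= off <= 14:
                raise ValueError(f"offset for length {length} outside [10, 14]")
        if sum(self.contaminant_fracs.values()) >= 1.0:
            raise ValueError("contaminant fractions must sum to < 1")

    def replace(self, **kwargs) -> "StagePreset":
        return dataclasses.replace(self, **kwargs)


_DEFAULT_CONTAM = {
    "rRNA": 0.15, "tRNA": 0.05, "snRNA": 0.01,
    "snoRNA": 0.01, "miRNA": 0.005, "lncRNA": 0.02,
}
_OFFSETS = {27: 12, 28: 12, 29: 13}

#: Stage presets. Dry-seed region weights are the printed 3.57/92.30/4.13
#: percentages; imbibed stages sit inside the reported 96-98% CDS range.
#: The dry start-pause weight is set so that roughly 7% of mRNA P sites sit
#: on the start codon (about 1-2% for imbibed stages).
PRESETS: dict[str, StagePreset] = {
    "dry": StagePreset(
        name="dry",
        length_probs={27: 0.25, 28: 0.50, 29: 0.25},
        p_offset_by_length=_OFFSETS,
        frame_error=0.08,
        region_weights=(0.0357, 0.9230, 0.0413),
        start_pause_weight=14.0,
        codon_pause_weights=codon_weights(
            {"G": 2.5, "D": 2.2, "Y": 2.0},
            {"TAG": 0.20, "TAA": 0.05, "TGA": 0.05},
        ),
        stop_minus4_weight=2.5,
        plus1_stop_fraction=0.20,
        contaminant_fracs=dict(_DEFAULT_CONTAM),
    ),
    "hai6": StagePreset(
        name="hai6",
        length_probs={27: 0.25, 28: 0.48, 29: 0.27},
        p_offset_by_length=_OFFSETS,
        frame_error=0.05,
        region_weights=(0.023, 0.967, 0.010),
        start_pause_weight=2.5,
        codon_pause_weights=codon_weights({"G": 2.4, "P": 2.2, "D": 2.0}, 0.02),
        stop_minus4_weight=2.5,
        plus1_stop_fraction=0.15,
        contaminant_fracs=dict(_DEFAULT_CONTAM),
    ),
    "hai26": StagePreset(
        name="hai26",
        length_probs={27: 0.24, 28: 0.46, 29: 0.30},
        p_offset_by_length=_OFFSETS,
        frame_error=0.05,
        region_weights=(0.022, 0.969, 0.009),
        start_pause_weight=1.5,
        codon_pause_weights=codon_weights(
            {"G": 2.4, "D": 2.2, "Y": 2.0, "P": 1.9}, 0.02
        ),
        stop_minus4_weight=2.5,
        plus1_stop_fraction=0.15,
        contaminant_fracs=dict(_DEFAULT_CONTAM),
    ),
    "hai48": StagePreset(
        name="hai48",
        length_probs={27: 0.22, 28: 0.36, 29: 0.42},
        p_offset_by_length=_OFFSETS,
        frame_error=0.05,
        region_weights=(0.020, 0.971, 0.009),
        start_pause_weight=1.5,
        codon_pause_weights=codon_weights(
            {"G": 2.4, "D": 2.2, "Y": 2.0, "P": 1.9}, 0.02
        ),
        stop_minus4_weight=2.5,
        plus1_stop_fraction=0.15,
        contaminant_fracs=dict(_DEFAULT_CONTAM),
    ),
    "hai72": StagePreset(
        name="hai72",
        length_probs={27: 0.20, 28: 0.34, 29: 0.46},
        p_offset_by_length=_OFFSETS,
        frame_error=0.05,
        region_weights=(0.019, 0.973, 0.008),
        start_pause_weight=1.5,
        codon_pause_weights=codon_weights(
            {"G": 2.4, "D": 2.2, "Y": 2.0, "P": 1.9}, 0.02
        ),
        stop_minus4_weight=2.5,
        plus1_stop_fraction=0.15,
        contaminant_fracs=dict(_DEFAULT_CONTAM),
    ),
}

_NT = np.array(list("ACGT"))


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_NT[rng.integers(0, 4, n)])


def _rand_codons(rng: np.random.Generator, n: int) -> str:
    idx = rng.integers(0, len(_NONSTOP_CODONS), n)
    return "".join(_NONSTOP_CODONS[i] for i in idx)


_CONTAM_LENGTHS = {"rRNA": 1500, "tRNA": 76, "snRNA": 150, "snoRNA": 110, "miRNA": 90}


def simulate_reference(
    n_mrna: int = 60,
    n_lncrna: int = 12,
    n_contam: int = 10,
    kozak_fraction: float = 0.25,
    uorf_fraction: float = 0.3,
    seed: int = 0,
    utr5_range: tuple[int, int] = (50, 120),
    min_uorf_bp: int = 63,
) -> tuple[ReferenceSet, pd.DataFrame]:
    """Generate a toy transcriptome: mRNAs with AUG..stop CDSs, optional
    Kozak context (A at -3/-2, G at +4) and 5'-UTR ORFs longer than 60 bp,
    lncRNAs split into ORF-bearing and ORF-free halves, and contaminant
    transcripts cycled over rRNA/tRNA/snRNA/snoRNA/miRNA.

    Returns the ReferenceSet plus a gene-truth table recording the planted
    Kozak flags and ORF intervals. Deterministic in ``seed``.
    """
    rng = np.random.default_rng(seed)
    transcripts: dict[str, TranscriptModel] = {}
    truth_rows = []

    n_kozak = int(round(kozak_fraction * n_mrna))
    n_uorf = int(round(uorf_fraction * n_mrna))
    if n_uorf > 0 and utr5_range[1] < min_uorf_bp + 6:
        raise ValueError(
            f"5' UTR upper bound {utr5_range[1]} too short to host a"
            f" {min_uorf_bp}-bp uORF"
        )
    idx = rng.permutation(n_mrna)
    kozak_set = set(idx[:n_kozak])
    uorf_set = set(idx[n_mrna - n_uorf:]) if n_uorf else set()

    for i in range(n_mrna):
        gid = f"G{i:04d}"
        tid = f"{gid}.1"
        host_uorf = i in uorf_set
        lo = max(utr5_range[0], min_uorf_bp + 10) if host_uorf else utr5_range[0]
        utr5_len = int(rng.integers(lo, utr5_range[1] + 1))
        n_codons = int(rng.integers(60, 201))
        utr3_len = int(rng.integers(40, 81))
        utr5 = list(_rand_seq(rng, utr5_len))
        cds = "ATG" + _rand_codons(rng, n_codons - 2) + _STOP_CODONS[
            int(rng.integers(0, 3))
        ]
        utr3 = _rand_seq(rng, utr3_len)

        uorf_start = uorf_end = -1
        if host_uorf:
            max_codons = min(30, (utr5_len - 4) // 3)
            m = int(rng.integers(21, max_codons + 1)) if max_codons > 21 else 21
            orf = "ATG" + _rand_codons(rng, m - 2) + _STOP_CODONS[
                int(rng.integers(0, 3))
            ]
            uorf_start = int(rng.integers(0, utr5_len - 3 * m - 4 + 1))
            uorf_end = uorf_start + 3 * m
            utr5[uorf_start:uorf_end] = list(orf)
        if i in kozak_set:
            utr5[utr5_len - 3] = "A"
            utr5[utr5_len - 2] = "A"
            cds = cds[:3] + "G" + cds[4:]

        seq = "".join(utr5) + cds + utr3
        transcripts[tid] = TranscriptModel(
            transcript_id=tid, gene_id=gid, biotype="mRNA", sequence=seq,
            cds_start=utr5_len, cds_end=utr5_len + len(cds),
        )
        truth_rows.append(
            {"transcript_id": tid, "gene_id": gid, "biotype": "mRNA",
             "kozak": i in kozak_set, "orf_start": uorf_start, "orf_end": uorf_end}
        )

    n_orf_lnc = (n_lncrna + 1) // 2
    for i in range(n_lncrna):
        tid = f"LNC{i:03d}"
        length = int(rng.integers(250, 501))
        seq = _rand_seq(rng, length)
        orf_start = orf_end = -1
        if i < n_orf_lnc:
            m = int(rng.integers(22, 36))
            orf = "ATG" + _rand_codons(rng, m - 2) + _STOP_CODONS[
                int(rng.integers(0, 3))
            ]
            orf_start = int(rng.integers(0, length - 3 * m + 1))
            orf_end = orf_start + 3 * m
            seq = seq[:orf_start] + orf + seq[orf_end:]
        else:
            while "ATG" in seq:
                j = seq.index("ATG")
                seq = seq[:j + 2] + "C" + seq[j + 3:]
        transcripts[tid] = TranscriptModel(
            transcript_id=tid, gene_id=tid, biotype="lncRNA", sequence=seq
        )
        truth_rows.append(
            {"transcript_id": tid, "gene_id": tid, "biotype": "lncRNA",
             "kozak": False, "orf_start": orf_start, "orf_end": orf_end}
        )

    contam_kinds = ("rRNA", "tRNA", "snRNA", "snoRNA", "miRNA")
    for i in range(n_contam):
        kind = contam_kinds[i % len(contam_kinds)]
        tid = f"{kind}_{i:03d}"
        seq = _rand_seq(rng, _CONTAM_LENGTHS[kind])
        transcripts[tid] = TranscriptModel(
            transcript_id=tid, gene_id=tid, biotype=kind, sequence=seq
        )
        truth_rows.append(
            {"transcript_id": tid, "gene_id": tid, "biotype": kind,
             "kozak": False, "orf_start": -1, "orf_end": -1}
        )

    return ReferenceSet(transcripts=transcripts), pd.DataFrame(truth_rows)


class _TranscriptSampler:
    """Pre-computed P-site candidate positions and weights for one mRNA."""

    def __init__(self, t: TranscriptModel, preset: StagePreset, uorf: tuple[int, int] | None):
        self.t = t
        positions = []
        weights = []
        n_codons = t.cds_len // 3
        for k in range(n_codons):
            pos = t.cds_start + 3 * k
            codon = t.sequence[pos:pos + 3]
            w = preset.codon_pause_weights.get(codon, 1.0)
            if k == 0:
                w *= preset.start_pause_weight
            positions.append(pos)
            weights.append(w)
        minus4 = t.cds_end - 7
        if minus4 >= t.cds_start:
            positions.append(minus4)
            weights.append(preset.stop_minus4_weight)
        self.cds_positions = np.array(positions)
        self.cds_cum = np.cumsum(np.array(weights, dtype=float))
        self.uorf = uorf  # (start, end) on transcript, or None


def _find_uorf(t: TranscriptModel) -> tuple[int, int] | None:
    from .orfs import predict_orfs

    if not t.is_mrna or t.cds_start == 0:
        return None
    orfs = predict_orfs(t.sequence[: t.cds_start])
    if not orfs:
        return None
    longest = max(orfs, key=lambda o: o.length_bp)
    return longest.start, longest.end


def simulate_footprints(
    ref: ReferenceSet,
    preset: StagePreset,
    n_reads: int,
    seed: int = 0,
    add_adaptor: bool = True,
) -> tuple[list[tuple[str, str, str]], pd.DataFrame]:
    """Sample ribosome footprints from a reference under one stage preset.

    Each read is a transcript subsequence whose 5' end sits at
    ``true P site - offset[length]``. mRNA P sites are drawn region-first
    (UTR5/CDS/UTR3 per the preset shares), with CDS positions weighted by
    codon pause weights, the start-codon weight and the stop-upstream peak,
    then jittered by the frame-error and near-stop +1-shift processes.
    UTR5 reads concentrate in a uORF when the transcript has one, as do
    lncRNA reads in a lncRNA ORF. Contaminant reads are uniform. Footprints
    that would exit the transcript are resampled, never emitted.

    Returns FASTQ-ready records ``(read_id, sequence, quality)`` and the
    per-read truth table.
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    rng = np.random.default_rng(seed)

    categories = list(preset.contaminant_fracs)
    for cat in categories:
        if not ref.by_category(cat):
            raise ValueError(f"preset requests contaminant category {cat!r}"
                             " absent from the reference")
    probs = [preset.contaminant_fracs[c] for c in categories]
    p_mrna = 1.0 - sum(probs)
    class_names = ["mRNA"] + categories
    class_probs = np.array([p_mrna] + probs)

    pools: dict[str, tuple[list[TranscriptModel], np.ndarray]] = {}
    for cat in class_names:
        txs = ref.by_category(cat)
        if cat == "mRNA" and not txs:
            raise ValueError("reference has no mRNA")
        ab = rng.lognormal(0.0, 1.0, len(txs))
        pools[cat] = (txs, np.cumsum(ab / ab.sum()) if txs else np.array([]))

    samplers = {
        t.transcript_id: _TranscriptSampler(t, preset, _find_uorf(t))
        for t in ref.mrnas()
    }
    lnc_orfs = {}
    for t in ref.by_category("lncRNA"):
        from .orfs import predict_orfs

        found = predict_orfs(t.sequence)
        lnc_orfs[t.transcript_id] = (
            max(found, key=lambda o: o.length_bp) if found else None
        )

    lengths = sorted(preset.length_probs)
    length_cum = np.cumsum([preset.length_probs[L] for L in lengths])
    region_cum = np.cumsum(preset.region_weights)

    reads: list[tuple[str, str, str]] = []
    truth_rows = []
    for i in range(n_reads):
        # class and (for mRNA) region are drawn once per read; failed
        # placements resample transcript/position/length within them, so the
        # emitted class and region marginals match the preset exactly
        cat = class_names[int(np.searchsorted(np.cumsum(class_probs), rng.random()))]
        r = int(np.searchsorted(region_cum, rng.random()))
        for _attempt in range(500):
            txs, cum = pools[cat]
            t = txs[int(np.searchsorted(cum, rng.random()))]
            L = lengths[int(np.searchsorted(length_cum, rng.random()))]
            if t.length < L:
                continue
            offset = preset.p_offset_by_length[L]

            if cat == "mRNA":
                s = samplers[t.transcript_id]
                if r == 0:
                    if t.cds_start == 0:
                        continue
                    if s.uorf is not None and rng.random() < 0.8:
                        u0, u1 = s.uorf
                        k = int(rng.integers(0, (u1 - u0) // 3))
                        psite = u0 + 3 * k
                    else:
                        psite = int(rng.integers(0, t.cds_start))
                elif r == 1:
                    j = int(np.searchsorted(s.cds_cum, rng.random() * s.cds_cum[-1]))
                    psite = int(s.cds_positions[j])
                else:
                    if t.cds_end >= t.length:
                        continue
                    psite = int(rng.integers(t.cds_end, t.length))
                if t.cds_end - 12 <= psite < t.cds_end and rng.random() < preset.plus1_stop_fraction:
                    psite += 1
                if rng.random() < preset.frame_error:
                    psite += 1 if psite == 0 else int(rng.choice((-1, 1)))
                p5 = psite - offset
            elif cat == "lncRNA":
                orf = lnc_orfs[t.transcript_id]
                if orf is not None and rng.random() < 0.8:
                    k = int(rng.integers(0, orf.length_bp // 3))
                    psite = orf.start + 3 * k
                else:
                    psite = int(rng.integers(0, t.length))
                p5 = psite - offset
            else:
                p5 = int(rng.integers(0, t.length - L + 1))
                psite = -1

            if p5 < 0 or p5 + L > t.length:
                continue
            seq = t.sequence[p5:p5 + L]
            read_id = f"r{i:06d}"
            full = seq + ADAPTOR if add_adaptor else seq
            reads.append((read_id, full, "I" * len(full)))
            if cat == "mRNA":
                frame = (psite - t.cds_start) % 3
                region = t.region_of(psite)
            else:
                frame, region = -1, "nc"
            truth_rows.append(
                {"read_id": read_id, "transcript_id": t.transcript_id,
                 "category": cat, "psite": psite, "p5": p5,
                 "length": L, "region": region, "frame": frame}
            )
            break
        else:
            raise RuntimeError("could not place footprint after 500 attempts")

    return reads, pd.DataFrame(truth_rows)


def write_fastq(reads: list[tuple[str, str, str]]) -> str:
    return "".join(f"@{rid}\n{seq}\n+\n{qual}\n" for rid, seq, qual in reads)


def parse_fastq(text: str) -> list[tuple[str, str]]:
    lines = text.splitlines()
    return [
        (lines[i][1:].split()[0], lines[i + 1]) for i in range(0, len(lines) - 3, 4)
    ]


def simulate_expression_counts(
    ref: ReferenceSet,
    design: list[tuple[str, int]] | None = None,
    te_shift_spec: dict | None = None,
    seed: int = 0,
    dispersion_range: tuple[float, float] = (0.02, 0.2),
) -> tuple[CountMatrix, CountMatrix, pd.DataFrame]:
    """NB-distributed ribo/total count matrices with optional planted TE
    shifts.

    Features are mRNA genes plus lncRNA transcripts. Per-feature baseline
    means are log-normal; per-stage expression effects are shared between
    the two assays (so the interaction is null unless a shift is planted);
    per-sample size factors are uniform on [0.7, 1.4]. ``te_shift_spec``
    is either a mapping ``feature -> log2 TE shift`` or
    ``{"fraction": f, "log2fc": x}``; shifts apply to the ribo assay in
    every stage after the first.
    """
    if design is None:
        design = [(s, 3) for s in STAGES]
    if len(design) < 2 or any(reps < 2 for _, reps in design):
        raise DesignError("design needs >= 2 stages and >= 2 replicates each")
    rng = np.random.default_rng(seed)

    features = [t.gene_id for t in ref.mrnas()] + [
        t.transcript_id for t in ref.by_category("lncRNA")
    ]
    n = len(features)
    base = rng.lognormal(np.log(150.0), 1.0, n)
    ribo_scale = rng.lognormal(0.0, 0.3, n)
    disp = rng.uniform(*dispersion_range, n)

    stages = [s for s, _ in design]
    stage_eff = {
        s: (np.ones(n) if j == 0 else rng.lognormal(0.0, 0.2, n))
        for j, s in enumerate(stages)
    }

    shifts = np.zeros(n)
    if te_shift_spec:
        if "fraction" in te_shift_spec:
            k = int(round(te_shift_spec["fraction"] * n))
            chosen = rng.choice(n, size=k, replace=False)
            shifts[chosen] = te_shift_spec["log2fc"]
        else:
            for f, x in te_shift_spec.items():
                shifts[features.index(f)] = x

    cols, meta_rows = [], []
    ribo_cols, total_cols = {}, {}
    for stage_idx, (stage, reps) in enumerate(design):
        for rep in range(1, reps + 1):
            for assay in ("ribo", "total"):
                sf = rng.uniform(0.7, 1.4)
                mu = base * stage_eff[stage] * sf
                if assay == "ribo":
                    mu = mu * ribo_scale
                    if stage_idx > 0:
                        mu = mu * 2.0 ** shifts
                r_param = 1.0 / disp
                counts = rng.negative_binomial(r_param, r_param / (r_param + mu))
                sample = f"{assay}_{stage}_r{rep}"
                (ribo_cols if assay == "ribo" else total_cols)[sample] = counts
                meta_rows.append(
                    {"sample": sample, "stage": stage, "replicate": rep,
                     "assay": assay, "size_factor_true": sf}
                )

    meta = pd.DataFrame(meta_rows).set_index("sample")
    ribo = CountMatrix(
        counts=pd.DataFrame(ribo_cols, index=features),
        samples=meta[meta["assay"] == "ribo"][["stage", "replicate", "assay"]],
    )
    total = CountMatrix(
        counts=pd.DataFrame(total_cols, index=features),
        samples=meta[meta["assay"] == "total"][["stage", "replicate", "assay"]],
    )
    truth = pd.DataFrame(
        {"feature": features, "base_mean": base, "ribo_scale": ribo_scale,
         "dispersion": disp, "te_log2fc": shifts}
    ).set_index("feature")
    return ribo, total, truth
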