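"""End-to-end orchestration: simulate -> trim -> map -> calibrate ->
metagene -> occupancy -> TE -> uORF/lncRNA -> report.

A run is fully determined by its config (including the mandatory seed):
the global seed is split deterministically per stage/replicate, every
output file is written with stable ordering and float formatting, and the
run log records a checksum per artifact, so identical configs produce
byte-identical bundles.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotation, difftrans, mapping, occupancy, orfs, psite, simulate

_FLOAT_FMT = "%.6g"


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    seed: int
    stages: tuple[str, ...] = simulate.STAGES
    replicates: int = 3
    n_reads: int = 20_000
    n_mrna: int = 60
    n_lncrna: int = 12
    n_contam: int = 10
    kozak_fraction: float = 0.25
    uorf_fraction: float = 0.3
    adaptor: str = mapping.DEFAULT_ADAPTOR
    min_len: int = mapping.DEFAULT_MIN_LEN
    prop_threshold: float = 0.10
    count_threshold: int = 30
    uorf_min_bp: int = 60
    rpkm_min: float = 5.0
    padj_cut: float = 0.05
    fold_cut: float = 2.0
    start_window: tuple[int, int] = psite.START_WINDOW
    stop_window: tuple[int, int] = psite.STOP_WINDOW
    offset_min_support: int = psite.MIN_SUPPORT
    te_shift_spec: dict | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("field 'seed' is mandatory for simulate runs")
        for name in ("n_reads", "n_mrna", "replicates", "min_len", "uorf_min_bp",
                     "count_threshold"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"field {name!r} must be positive")
        for name in ("prop_threshold", "rpkm_min", "padj_cut", "fold_cut"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"field {name!r} must be positive")
        unknown = [s for s in self.stages if s not in simulate.PRESETS]
        if unknown:
            raise ConfigError(
                f"field 'stages' names unknown presets {unknown};"
                f" known: {sorted(simulate.PRESETS)}"
            )
        if len(self.stages) < 2:
            raise ConfigError("field 'stages' must list at least two stages")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(d) - known
        if bad:
            raise ConfigError(f"unknown config fields: {sorted(bad)}")
        d = dict(d)
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        for key in ("start_window", "stop_window"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _child_seed(seed: int, *key: int) -> int:
    return int(np.random.SeedSequence([seed, *key]).generate_state(1)[0] % (2**31))


def _write(path: Path, text: str, log: dict) -> None:
    path.write_text(text)
    log[path.name] = hashlib.sha256(text.encode()).hexdigest()


def _tsv(df: pd.DataFrame, index: bool = True) -> str:
    return df.to_csv(sep="\t", float_format=_FLOAT_FMT, index=index)


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute every stage on simulated data and write the result bundle.

    Returns the run log (file name -> sha256, plus seed and summary
    numbers). Identical config + seed reproduce identical bundles.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    checksums: dict[str, str] = {}

    ref, gene_truth = simulate.simulate_reference(
        n_mrna=config.n_mrna, n_lncrna=config.n_lncrna, n_contam=config.n_contam,
        kozak_fraction=config.kozak_fraction, uorf_fraction=config.uorf_fraction,
        seed=_child_seed(config.seed, 0),
    )
    fasta, gff, biotab = annotation.write_reference(ref)
    _write(out / "reference.fasta", fasta, checksums)
    _write(out / "reference.gff3", gff, checksums)
    _write(out / "biotypes.tsv", biotab, checksums)
    _write(out / "gene_truth.tsv", _tsv(gene_truth, index=False), checksums)

    psites_by_sample: dict[tuple[str, int], list[psite.PsiteRecord]] = {}
    tallies_frames = []
    meta_frames = []
    offset_frames = []
    for si, stage in enumerate(config.stages):
        preset = simulate.PRESETS[stage]
        for rep in range(1, config.replicates + 1):
            sseed = _child_seed(config.seed, si + 1, rep)
            reads, truth = simulate.simulate_footprints(
                ref, preset, config.n_reads, seed=sseed
            )
            tag = f"{stage}_r{rep}"
            _write(out / f"reads_{tag}.fastq", simulate.write_fastq(reads), checksums)
            _write(out / f"truth_{tag}.tsv", _tsv(truth, index=False), checksums)

            trimmed = []
            for rid, seq, _q in reads:
                t = mapping.trim_read(seq, config.adaptor, config.min_len)
                if t is not None:
                    trimmed.append((rid, t))
            fps, tally, _unmapped = mapping.hierarchical_map(trimmed, ref)
            tally.insert(0, "sample", tag)
            tallies_frames.append(tally)
            _write(out / f"alignments_{tag}.tsv",
                   _tsv(mapping.footprints_to_frame(fps), index=False), checksums)

            offsets = psite.estimate_offsets(
                fps, ref, min_support=config.offset_min_support
            )
            odf = offsets.to_frame()
            odf.insert(0, "sample", tag)
            offset_frames.append(odf)
            records, _stats = psite.assign_psites(fps, offsets, ref)
            psites_by_sample[(stage, rep)] = records
            _write(out / f"psites_{tag}.tsv",
                   _tsv(psite.psites_to_frame(records), index=False), checksums)

            profiles = []
            for anchor, window in (("start", config.start_window),
                                   ("stop", config.stop_window)):
                for mode in ("p5", "p3", "psite"):
                    events = records if mode == "psite" else fps
                    prof = psite.metagene(events, ref, anchor=anchor,
                                          mode=mode, window=window)
                    df = prof.counts.reset_index()
                    df.insert(0, "mode", mode)
                    df.insert(0, "anchor", anchor)
                    profiles.append(df)
            _write(out / f"metagene_{tag}.tsv",
                   _tsv(pd.concat(profiles, ignore_index=True), index=False),
                   checksums)

            try:
                frames, length_shares = psite.frame_stats(records)
            except ValueError:
                frames = pd.Series(dtype=float)
                length_shares = pd.Series(dtype=float)
            fdf = pd.DataFrame({"frame": frames.index, "fraction": frames.values})
            ldf = pd.DataFrame({"length": length_shares.index,
                                "share": length_shares.values})
            _write(out / f"frames_{tag}.tsv", _tsv(fdf, index=False), checksums)
            _write(out / f"lengths_{tag}.tsv", _tsv(ldf, index=False), checksums)

    _write(out / "mapping_summary.tsv",
           _tsv(pd.concat(tallies_frames, ignore_index=True), index=False), checksums)
    _write(out / "offsets.tsv",
           _tsv(pd.concat(offset_frames, ignore_index=True), index=False), checksums)

    pct, pct_tests = occupancy.region_distribution(psites_by_sample,
                                                   baseline=config.stages[0])
    _write(out / "region_pct.tsv", _tsv(pct, index=False), checksums)
    _write(out / "region_tests.tsv", _tsv(pct_tests, index=False), checksums)
    frac, frac_tests = occupancy.start_codon_fraction(
        psites_by_sample, ref, window=config.start_window,
        baseline=config.stages[0],
    )
    _write(out / "start_fraction.tsv", _tsv(frac, index=False), checksums)
    _write(out / "start_fraction_tests.tsv", _tsv(frac_tests, index=False), checksums)

    codon_frames = []
    for stage in config.stages:
        pooled = [r for (s, _), recs in psites_by_sample.items() if s == stage
                  for r in recs]
        usage = occupancy.codon_usage_index(pooled, ref)
        df = usage.table.reset_index()
        df.insert(0, "stage", stage)
        codon_frames.append(df)
    _write(out / "codon_index.tsv",
           _tsv(pd.concat(codon_frames, ignore_index=True), index=False), checksums)

    # start-codon-enriched genes from the first (baseline) stage, pooled reps
    baseline_records = [r for (s, _), recs in psites_by_sample.items()
                        if s == config.stages[0] for r in recs]
    tallies = occupancy.gene_region_tallies(baseline_records, ref)
    enriched = occupancy.select_start_enriched(
        tallies, config.prop_threshold, config.count_threshold
    )
    _write(out / "start_enriched.tsv",
           _tsv(tallies.assign(enriched=[g in enriched for g in tallies.index])),
           checksums)

    cds_lengths = pd.Series({t.gene_id: t.cds_len for t in ref.mrnas()})
    gene_counts = {}
    for (stage, rep), records in psites_by_sample.items():
        if stage != config.stages[0]:
            continue
        c = pd.Series(0, index=cds_lengths.index, dtype=int)
        tl = occupancy.gene_region_tallies(records, ref)
        c.loc[tl.index] = tl["psites_cds_total"]
        gene_counts[f"{stage}_r{rep}"] = c
    base_counts = pd.DataFrame(gene_counts)
    base_rpkm = difftrans.rpkm(base_counts, cds_lengths)
    expressed = set(base_rpkm.index[(base_rpkm > config.rpkm_min).all(axis=1)])
    background = expressed - enriched
    motif_df = pd.DataFrame()
    consensus = ""
    try:
        motif_df, consensus = occupancy.start_context_test(enriched, background, ref)
    except ValueError:
        pass  # too few genes at this scale; reported empty
    _write(out / "motif.tsv", _tsv(motif_df.reset_index() if len(motif_df) else motif_df,
                                   index=False), checksums)

    design = [(s, config.replicates) for s in config.stages]
    ribo_cm, total_cm, count_truth = simulate.simulate_expression_counts(
        ref, design=design, te_shift_spec=config.te_shift_spec,
        seed=_child_seed(config.seed, 99),
    )
    _write(out / "counts_ribo.tsv", _tsv(ribo_cm.counts), checksums)
    _write(out / "counts_total.tsv", _tsv(total_cm.counts), checksums)

    te_frames = []
    for a, b in zip(config.stages[:-1], config.stages[1:]):
        res = difftrans.te_lrt(ribo_cm, total_cm, (a, b),
                               padj_cut=config.padj_cut,
                               lfc_cut=float(np.log2(config.fold_cut)))
        res = res.reset_index(names="feature")
        res.insert(0, "contrast", f"{a}_vs_{b}")
        te_frames.append(res)
    te_all = pd.concat(te_frames, ignore_index=True)
    _write(out / "te_lrt.tsv", _tsv(te_all, index=False), checksums)

    uorfs = orfs.annotate_uorfs(ref, min_len_bp=config.uorf_min_bp)
    _write(out / "uorfs.gff3", orfs.uorfs_to_gff(uorfs), checksums)

    cds_features = pd.DataFrame(
        [
            {"feature_id": t.gene_id, "transcript_id": t.transcript_id,
             "start": t.cds_start, "end": t.cds_end}
            for t in ref.mrnas()
        ]
    )
    uorf_cols, cds_cols, meta_rows = {}, {}, []
    for (stage, rep), records in sorted(psites_by_sample.items()):
        tag = f"ribo_{stage}_r{rep}"
        uorf_cols[tag] = orfs.count_features(records, uorfs) if len(uorfs) else pd.Series(dtype=int)
        cds_cols[tag] = orfs.count_features(records, cds_features)
        meta_rows.append({"sample": tag, "stage": stage, "replicate": rep,
                          "assay": "ribo"})
    meta = pd.DataFrame(meta_rows).set_index("sample")
    shift_frames = []
    if len(uorfs):
        uorf_cm = difftrans.CountMatrix(counts=pd.DataFrame(uorf_cols), samples=meta)
        cds_cm = difftrans.CountMatrix(counts=pd.DataFrame(cds_cols), samples=meta)
        uorf_lengths = uorfs.set_index("feature_id")["length_bp"]
        uorf_to_gene = uorfs.set_index("feature_id")["gene_id"]
        for a, b in zip(config.stages[:-1], config.stages[1:]):
            res = orfs.uorf_morf_shift(
                uorf_cm, cds_cm, (a, b), uorf_lengths, cds_lengths,
                uorf_to_gene, rpkm_min=config.rpkm_min, alpha=config.padj_cut,
            )
            res = res.reset_index()
            res.insert(0, "contrast", f"{a}_vs_{b}")
            shift_frames.append(res)
    shifts = (pd.concat(shift_frames, ignore_index=True)
              if shift_frames else pd.DataFrame())
    _write(out / "uorf_shifts.tsv", _tsv(shifts, index=False), checksums)

    lnc = ref.by_category("lncRNA")
    lnc_lengths = pd.Series({t.transcript_id: t.length for t in lnc})
    orf_bearing = {
        t.transcript_id for t in lnc if orfs.predict_orfs(t.sequence)
    }
    lnc_frames = []
    for a, b in zip(config.stages[:-1], config.stages[1:]):
        res = orfs.lncrna_translation(
            ribo_cm, total_cm, (a, b), lnc_lengths, orf_bearing,
            rpkm_min=config.rpkm_min,
        )
        res = res.reset_index(names="feature")
        res.insert(0, "contrast", f"{a}_vs_{b}")
        lnc_frames.append(res)
    _write(out / "lncrna_te.tsv",
           _tsv(pd.concat(lnc_frames, ignore_index=True), index=False), checksums)

    log = {
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "n_start_enriched": len(enriched),
        "motif_consensus": consensus,
        "checksums": checksums,
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True, default=str))
    return log
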