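"""Differential translation: median-of-ratios normalization, rpkm,
negative-binomial GLM tests, TE-pattern classification, and Fisher term
enrichment.

Translation efficiency (TE) is the ratio of ribosome-associated to total
RNA abundance. A TE change between two conditions is tested with the
interaction likelihood-ratio test: per feature, a negative-binomial GLM
(log link, size-factor offsets) with design ``~ assay + condition +
assay:condition`` is compared against the reduced model without the
interaction term; the statistic is referred to chi-squared with one degree
of freedom, and the interaction coefficient divided by ln 2 is the log2 TE
change.

Dispersion handling is deliberately simple: a per-feature method-of-moments
estimate (unbiased within-group variances), floored at 1e-8 and shrunk 50%
toward the mean dispersion of features in the same expression decile. This
stabilizes small-replicate estimates without an empirical-Bayes machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

LN2 = float(np.log(2.0))

DISPERSION_FLOOR = 1e-8
MAX_ITER = 100
TOL = 1e-8


class DesignError(ValueError):
    pass


@dataclass
class CountMatrix:
    """Feature x sample integer counts with per-sample metadata.

    ``samples`` is indexed by sample id and carries columns ``stage``,
    ``replicate`` and ``assay`` (one of ``ribo``/``total``).
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.samples.index):
            raise DesignError("counts columns and sample metadata index differ")
        for col in ("stage", "replicate", "assay"):
            if col not in self.samples.columns:
                raise DesignError(f"sample metadata lacks column {col!r}")
        if (self.counts.values < 0).any():
            raise DesignError("negative counts")

    def subset(
        self,
        stages: tuple[str, ...] | list[str] | None = None,
        assay: str | None = None,
        features: list[str] | None = None,
    ) -> "CountMatrix":
        meta = self.samples
        if stages is not None:
            meta = meta[meta["stage"].isin(list(stages))]
        if assay is not None:
            meta = meta[meta["assay"] == assay]
        counts = self.counts.loc[:, meta.index]
        if features is not None:
            counts = counts.loc[features]
        return CountMatrix(counts=counts, samples=meta.copy())

    @property
    def assays(self) -> list[str]:
        return sorted(self.samples["assay"].unique())


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    Only features with a nonzero count in every sample contribute; the
    factor of a sample is the median over those features of the count
    divided by the feature's geometric mean across samples.
    """
    positive = counts[(counts > 0).all(axis=1)]
    if positive.empty:
        raise DesignError("no feature has nonzero counts in all samples")
    log_geomean = np.log(positive).mean(axis=1)
    ratios = np.log(positive).sub(log_geomean, axis=0)
    return pd.Series(
        np.exp(np.median(ratios, axis=0)), index=counts.columns, name="size_factor"
    )


def rpkm(
    counts: pd.DataFrame | pd.Series,
    lengths: pd.Series,
    total_reads: pd.Series | float | None = None,
) -> pd.DataFrame | pd.Series:
    """reads / (length/1000 * total/1e6), applied to (normalized) counts.

    ``total_reads`` defaults to the per-sample column sums of ``counts``.
    """
    if total_reads is None:
        total_reads = counts.sum(axis=0)
    lengths = lengths.reindex(counts.index)
    if (lengths <= 0).any():
        raise DesignError("non-positive feature length")
    denom = np.outer(lengths / 1e3, np.atleast_1d(total_reads) / 1e6)
    if isinstance(counts, pd.Series):
        return counts / denom[:, 0]
    return counts / pd.DataFrame(denom, index=counts.index, columns=counts.columns)


def bh_adjust(p: pd.Series) -> pd.Series:
    """Benjamini-Hochberg adjustment; NaN p-values are excluded from m."""
    out = pd.Series(np.nan, index=p.index, dtype=float)
    ok = p.notna()
    if ok.any():
        out[ok] = multipletests(p[ok].values, method="fdr_bh")[1]
    return out


def estimate_dispersions(
    counts: pd.DataFrame,
    sf: pd.Series,
    groups: pd.Series,
    shrink: float = 0.5,
    n_bins: int = 10,
) -> pd.Series:
    """Per-feature NB dispersion: pooled method-of-moments across the
    design groups, floored, then shrunk toward the expression-decile trend.
    """
    normed = counts / sf
    num = np.zeros(len(counts))
    den = np.zeros(len(counts))
    for g in groups.unique():
        cols = groups.index[groups == g]
        if len(cols) < 2:
            continue
        sub = normed[cols]
        m = sub.mean(axis=1).values
        v = sub.var(axis=1, ddof=1).values
        w = len(cols) - 1
        num += w * (v - m)
        den += w * m**2
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(den > 0, num / den, DISPERSION_FLOOR)
    raw = np.maximum(raw, DISPERSION_FLOOR)
    raw = pd.Series(raw, index=counts.index)

    base_mean = normed.mean(axis=1)
    try:
        bins = pd.qcut(base_mean.rank(method="first"), q=n_bins, labels=False)
    except ValueError:
        bins = pd.Series(0, index=base_mean.index)
    trend = raw.groupby(bins).transform("mean")
    disp = (1 - shrink) * raw + shrink * trend
    return np.maximum(disp, DISPERSION_FLOOR)


def _fit_nb(y, X, offset, alpha):
    model = sm.GLM(
        np.asarray(y, dtype=float),
        X,
        family=sm.families.NegativeBinomial(alpha=max(alpha, DISPERSION_FLOOR)),
        offset=offset,
    )
    res = model.fit(maxiter=MAX_ITER, tol=TOL)
    if not np.all(np.isfinite(res.params)):
        raise ValueError("non-finite coefficients")
    return res


def _te_design(samples: pd.DataFrame, stages: tuple[str, str]) -> np.ndarray:
    assay = (samples["assay"] == "ribo").astype(float).values
    cond = (samples["stage"] == stages[1]).astype(float).values
    return np.column_stack([np.ones(len(samples)), assay, cond, assay * cond])


def te_lrt(
    ribo: CountMatrix,
    total: CountMatrix,
    stages: tuple[str, str],
    padj_cut: float = 0.05,
    lfc_cut: float = 1.0,
) -> pd.DataFrame:
    """Interaction likelihood-ratio test for translation-efficiency change.

    Returns a frame indexed by feature with columns baseMean, log2FC (the
    TE change), stat, p, padj, significant. Features with zero counts in
    every selected sample are dropped; non-converged fits get p = NaN and
    are excluded from the BH denominator.
    """
    r = ribo.subset(stages=stages)
    t = total.subset(stages=stages)
    if set(r.samples["stage"]) != set(stages) or set(t.samples["stage"]) != set(stages):
        raise DesignError(f"both stages {stages} must be present in both assays")
    r.samples["assay"] = "ribo"
    t.samples["assay"] = "total"
    common = r.counts.index.intersection(t.counts.index)
    counts = pd.concat([r.counts.loc[common], t.counts.loc[common]], axis=1)
    samples = pd.concat([r.samples, t.samples])
    counts.columns = samples.index = [
        f"{a}_{s}_{rep}" for a, s, rep in
        zip(samples["assay"], samples["stage"], samples["replicate"])
    ]

    keep = counts.sum(axis=1) > 0
    counts = counts[keep]
    sf = size_factors(counts)
    offset = np.log(sf.values)
    groups = samples["assay"].str.cat(samples["stage"], sep=":")
    disp = estimate_dispersions(counts, sf, groups)

    X_full = _te_design(samples, stages)
    X_red = X_full[:, :3]
    base_mean = (counts / sf).mean(axis=1)

    stat = np.full(len(counts), np.nan)
    lfc = np.full(len(counts), np.nan)
    for i, (fid, y) in enumerate(counts.iterrows()):
        try:
            full = _fit_nb(y.values, X_full, offset, disp[fid])
            red = _fit_nb(y.values, X_red, offset, disp[fid])
            if not (full.converged and red.converged):
                continue
            stat[i] = max(2.0 * (full.llf - red.llf), 0.0)
            lfc[i] = full.params[3] / LN2
        except Exception:
            continue
    p = st.chi2.sf(stat, df=1)
    res = pd.DataFrame(
        {
            "baseMean": base_mean.values,
            "log2FC": lfc,
            "stat": stat,
            "p": p,
        },
        index=counts.index,
    )
    res["padj"] = bh_adjust(res["p"])
    res["significant"] = (res["padj"] < padj_cut) & (res["log2FC"].abs() >= lfc_cut)
    return res


def pairwise_de(
    counts: CountMatrix,
    stages: tuple[str, str],
    padj_cut: float = 0.05,
    lfc_cut: float = 1.0,
) -> pd.DataFrame:
    """Negative-binomial Wald test on the stage coefficient for one assay."""
    sub = counts.subset(stages=stages)
    if set(sub.samples["stage"]) != set(stages):
        raise DesignError(f"both stages {stages} must be present")
    mat = sub.counts[sub.counts.sum(axis=1) > 0]
    sf = size_factors(mat)
    offset = np.log(sf.values)
    disp = estimate_dispersions(mat, sf, sub.samples["stage"])
    cond = (sub.samples["stage"] == stages[1]).astype(float).values
    X = np.column_stack([np.ones(len(cond)), cond])
    base_mean = (mat / sf).mean(axis=1)

    stat = np.full(len(mat), np.nan)
    lfc = np.full(len(mat), np.nan)
    for i, (fid, y) in enumerate(mat.iterrows()):
        try:
            fit = _fit_nb(y.values, X, offset, disp[fid])
            if not fit.converged:
                continue
            stat[i] = fit.params[1] / fit.bse[1]
            lfc[i] = fit.params[1] / LN2
        except Exception:
            continue
    p = 2.0 * st.norm.sf(np.abs(stat))
    res = pd.DataFrame(
        {"baseMean": base_mean.values, "log2FC": lfc, "stat": stat, "p": p},
        index=mat.index,
    )
    res["padj"] = bh_adjust(res["p"])
    res["significant"] = (res["padj"] < padj_cut) & (res["log2FC"].abs() >= lfc_cut)
    return res


def classify_te_pattern(
    de_ribo: pd.DataFrame, de_total: pd.DataFrame
) -> pd.DataFrame:
    """Label each feature by where its change lives: R-only (ribosome-
    associated RNA), T-only (total RNA), additive (both), or none; the
    ``pattern`` column carries fold-change signs, e.g. "T+R+".
    """
    common = de_ribo.index.intersection(de_total.index)
    rows = []
    for fid in common:
        sig_r = bool(de_ribo.loc[fid, "significant"])
        sig_t = bool(de_total.loc[fid, "significant"])
        s_r = "+" if de_ribo.loc[fid, "log2FC"] > 0 else "-"
        s_t = "+" if de_total.loc[fid, "log2FC"] > 0 else "-"
        if sig_r and sig_t:
            label, pattern = "additive", f"T{s_t}R{s_r}"
        elif sig_r:
            label, pattern = "R-only", f"R{s_r}"
        elif sig_t:
            label, pattern = "T-only", f"T{s_t}"
        else:
            label, pattern = "none", ""
        rows.append({"feature": fid, "label": label, "pattern": pattern})
    return pd.DataFrame(rows).set_index("feature")


def term_enrichment(
    study: set[str], universe: set[str], term_map: dict[str, set[str]]
) -> pd.DataFrame:
    """One-sided Fisher (hypergeometric upper-tail) term enrichment + BH.

    ``study`` must be a subset of ``universe``; each term's gene set is
    intersected with the universe before testing.
    """
    if not universe:
        raise DesignError("empty universe")
    if not set(study) <= set(universe):
        raise DesignError("study set not contained in universe")
    N = len(universe)
    n = len(study)
    rows = []
    for term, genes in term_map.items():
        term_genes = set(genes) & set(universe)
        K = len(term_genes)
        k = len(term_genes & set(study))
        p = st.hypergeom.sf(k - 1, N, K, n) if K else 1.0
        rows.append(
            {"term": term, "overlap": k, "term_size": K,
             "study_size": n, "universe_size": N, "p": float(p)}
        )
    res = pd.DataFrame(rows).set_index("term")
    res["padj"] = bh_adjust(res["p"])
    return res
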