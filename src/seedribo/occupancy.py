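"""Region-occupancy percentages, start-codon stalling statistics, the
codon usage (pausing) index, start-codon-enriched gene selection, and
Kozak-context testing.

Region assignment uses the single P-site nucleotide, not the whole read,
so counts near UTR/CDS boundaries can differ from whole-read assignment by
at most one read length. Kozak numbering puts the A of the AUG at +1 with
no position zero; +4 is the first nucleotide after the start codon.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st

from .annotation import ReferenceSet
from .psite import PsiteRecord

SIGNIFICANCE_P = 1e-4  # per-position chi-squared threshold for the motif test
_RNA = str.maketrans("T", "U")


def gene_region_tallies(records: list[PsiteRecord], ref: ReferenceSet) -> pd.DataFrame:
    """Per-gene P-site counts: at the start codon, per region, and total."""
    rows: dict[str, dict] = {}
    for r in records:
        if r.region is None:
            continue
        t = ref[r.transcript_id]
        row = rows.setdefault(
            t.gene_id,
            {"gene_id": t.gene_id, "transcript_id": t.transcript_id,
             "psites_at_start": 0, "psites_cds_total": 0,
             "psites_utr5": 0, "psites_utr3": 0},
        )
        if r.region == "cds":
            row["psites_cds_total"] += 1
            if r.psite == t.cds_start:
                row["psites_at_start"] += 1
        elif r.region == "utr5":
            row["psites_utr5"] += 1
        else:
            row["psites_utr3"] += 1
    df = pd.DataFrame(
        rows.values(),
        columns=["gene_id", "transcript_id", "psites_at_start",
                 "psites_cds_total", "psites_utr5", "psites_utr3"],
    ).set_index("gene_id")
    df["total_psites"] = df[["psites_cds_total", "psites_utr5", "psites_utr3"]].sum(axis=1)
    return df


def _region_pct(records: list[PsiteRecord]) -> tuple[float, float, float]:
    counts = Counter(r.region for r in records if r.region is not None)
    total = sum(counts.values())
    if total == 0:
        raise ValueError("zero mRNA P sites")
    return tuple(100.0 * counts.get(k, 0) / total for k in ("utr5", "cds", "utr3"))


def region_distribution(
    per_replicate: dict[tuple[str, int], list[PsiteRecord]],
    baseline: str = "dry",
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-replicate UTR5/CDS/UTR3 percentages plus Welch t-tests of the
    baseline stage against every other stage, per region.

    ``per_replicate`` maps (stage, replicate) to that sample's P-site
    records. Percentages sum to 100 within each replicate.
    """
    rows = []
    for (stage, rep), records in sorted(per_replicate.items()):
        p5, pc, p3 = _region_pct(records)
        rows.append({"stage": stage, "replicate": rep,
                     "pct_utr5": p5, "pct_cds": pc, "pct_utr3": p3})
    pct = pd.DataFrame(rows)

    tests = []
    base = pct[pct["stage"] == baseline]
    for stage in pct["stage"].unique():
        if stage == baseline:
            continue
        other = pct[pct["stage"] == stage]
        if len(base) < 2 or len(other) < 2:
            continue
        for region in ("pct_utr5", "pct_cds", "pct_utr3"):
            t, p = st.ttest_ind(base[region], other[region], equal_var=False)
            tests.append(
                {"stage": stage, "region": region.removeprefix("pct_"),
                 "t": float(t), "p": float(p), "significant": bool(p < alpha)}
            )
    return pct, pd.DataFrame(tests, columns=["stage", "region", "t", "p", "significant"])


@dataclass
class CodonUsageTable:
    """Per-codon pausing index plus a separate start-codon-position entry.

    ``table`` is indexed by RNA codon with columns amino_acid, psite_count,
    psite_frac, codon_freq and index (= psite_frac / codon_freq, NaN for
    codons absent from the CDS set). The AUG row pools start and internal
    methionine codons; ``start_index`` isolates the start-codon position.
    """

    table: pd.DataFrame
    start_count: int
    start_index: float


def codon_usage_index(
    records: list[PsiteRecord],
    ref: ReferenceSet,
    gene_set: set[str] | None = None,
) -> CodonUsageTable:
    """Pausing index per codon from in-frame (frame 0) CDS P sites.

    index(c) = [P sites on c / all in-frame P sites] /
               [occurrences of c / all codon occurrences], with codon
    frequencies computed over the CDSs (start and stop codons included) of
    the same gene set.
    """
    mrnas = [
        t for t in ref.mrnas()
        if gene_set is None or t.gene_id in gene_set or t.transcript_id in gene_set
    ]
    if not mrnas:
        raise ValueError("empty gene set")
    tids = {t.transcript_id for t in mrnas}

    freq: Counter = Counter()
    n_codons = 0
    for t in mrnas:
        for pos in range(t.cds_start, t.cds_end - 2, 3):
            freq[t.sequence[pos:pos + 3]] += 1
            n_codons += 1

    psite_counts: Counter = Counter()
    start_count = 0
    total_psites = 0
    for r in records:
        if r.region != "cds" or r.frame != 0 or r.transcript_id not in tids:
            continue
        t = ref[r.transcript_id]
        codon = t.sequence[r.psite:r.psite + 3]
        psite_counts[codon] += 1
        total_psites += 1
        if r.psite == t.cds_start:
            start_count += 1
    if total_psites == 0:
        raise ValueError("no in-frame CDS P sites")

    rows = []
    for codon in sorted(set(freq) | set(psite_counts)):
        f = freq.get(codon, 0) / n_codons
        frac = psite_counts.get(codon, 0) / total_psites
        rows.append(
            {"codon": codon.translate(_RNA),
             "amino_acid": _translate(codon),
             "psite_count": psite_counts.get(codon, 0),
             "psite_frac": frac,
             "codon_freq": f,
             "index": frac / f if f > 0 else np.nan}
        )
    table = pd.DataFrame(rows).set_index("codon")
    start_freq = len(mrnas) / n_codons
    start_index = (start_count / total_psites) / start_freq
    return CodonUsageTable(table=table, start_count=start_count, start_index=start_index)


def _translate(codon: str) -> str:
    from Bio.Seq import Seq

    aa = str(Seq(codon).translate())
    return aa


def start_codon_fraction(
    per_replicate: dict[tuple[str, int], list[PsiteRecord]],
    ref: ReferenceSet,
    window: tuple[int, int] = (-48, 33),
    baseline: str = "dry",
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fraction of P sites exactly on a start codon, per replicate.

    ``frac_total`` uses all mRNA P-site records as denominator;
    ``frac_window`` restricts the denominator to P sites whose distance to
    a start codon lies inside the metaprofile window. Welch t-tests compare
    the baseline stage to every other stage on ``frac_total``.
    """
    rows = []
    for (stage, rep), records in sorted(per_replicate.items()):
        n_start = n_all = n_window = 0
        for r in records:
            if r.region is None:
                continue
            t = ref[r.transcript_id]
            n_all += 1
            d = r.psite - t.cds_start
            if window[0] <= d <= window[1]:
                n_window += 1
            if d == 0:
                n_start += 1
        if n_all == 0:
            raise ValueError("zero mRNA P sites")
        rows.append(
            {"stage": stage, "replicate": rep,
             "frac_total": n_start / n_all,
             "frac_window": n_start / n_window if n_window else np.nan}
        )
    frac = pd.DataFrame(rows)

    tests = []
    base = frac[frac["stage"] == baseline]
    for stage in frac["stage"].unique():
        if stage == baseline:
            continue
        other = frac[frac["stage"] == stage]
        if len(base) < 2 or len(other) < 2:
            continue
        t, p = st.ttest_ind(base["frac_total"], other["frac_total"], equal_var=False)
        tests.append({"stage": stage, "t": float(t), "p": float(p),
                      "significant": bool(p < alpha)})
    return frac, pd.DataFrame(tests, columns=["stage", "t", "p", "significant"])


def select_start_enriched(
    tallies: pd.DataFrame,
    prop_threshold: float = 0.10,
    count_threshold: int = 30,
) -> set[str]:
    """Start-codon-enriched genes: strictly more than ``prop_threshold`` of
    the gene's total P sites at the start codon AND strictly more than
    ``count_threshold`` start-codon P sites."""
    usable = tallies[tallies["total_psites"] > 0]
    prop = usable["psites_at_start"] / usable["total_psites"]
    mask = (prop > prop_threshold) & (usable["psites_at_start"] > count_threshold)
    return set(usable.index[mask])


def start_context_test(
    enriched: set[str],
    background: set[str],
    ref: ReferenceSet,
    window: tuple[int, int] = (-10, 10),
    min_genes: int = 20,
    significance_p: float = SIGNIFICANCE_P,
) -> tuple[pd.DataFrame, str]:
    """Per-position chi-squared test of nucleotide composition around the
    start codon, enriched vs background genes.

    Returns one row per Kozak position (nucleotide counts for both sets,
    chi2, p, significant at ``significance_p``, low_power when an expected
    cell is below 1) plus a consensus string over the window: the enriched
    set's modal nucleotide at significant or invariant positions, ``n``
    elsewhere (RNA alphabet).
    """
    def seqs_of(ids):
        out = []
        for t in ref.mrnas():
            if t.gene_id in ids or t.transcript_id in ids:
                out.append(t)
        return out

    enriched_t = seqs_of(enriched)
    background_t = seqs_of(background)
    if len(enriched_t) < min_genes or len(background_t) < min_genes:
        raise ValueError(
            f"need >= {min_genes} genes per set"
            f" (got {len(enriched_t)} vs {len(background_t)})"
        )

    positions = [k for k in range(window[0], window[1] + 1) if k != 0]
    rows = []
    consensus = []
    for k in positions:
        counts = {}
        for label, txs in (("enriched", enriched_t), ("background", background_t)):
            c = Counter()
            for t in txs:
                pos = t.cds_start + (k if k < 0 else k - 1)
                if 0 <= pos < t.length:
                    c[t.sequence[pos]] += 1
            counts[label] = c
        table = np.array(
            [[counts["enriched"].get(nt, 0), counts["background"].get(nt, 0)]
             for nt in "ACGT"]
        )
        nonzero = table[table.sum(axis=1) > 0]
        if len(nonzero) < 2:
            chi2, p, low_power = 0.0, 1.0, True
        else:
            chi2, p, _, expected = st.chi2_contingency(nonzero)
            low_power = bool((expected < 1).any())
        sig = bool(p < significance_p)
        enr = counts["enriched"]
        modal = max("ACGT", key=lambda nt: enr.get(nt, 0))
        invariant = sum(1 for nt in "ACGT" if enr.get(nt, 0) > 0) == 1
        consensus.append(modal.translate(_RNA) if (sig or invariant) else "n")
        row = {"position": k, "chi2": float(chi2), "p": float(p),
               "significant": sig, "low_power": low_power}
        for nt in "ACGT":
            row[f"enriched_{nt}"] = enr.get(nt, 0)
            row[f"background_{nt}"] = counts["background"].get(nt, 0)
        rows.append(row)
    return pd.DataFrame(rows).set_index("position"), "".join(consensus)
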