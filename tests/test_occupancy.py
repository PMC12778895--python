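import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from seedribo import simulate as sim
from seedribo.annotation import ReferenceSet
from seedribo.occupancy import (
    codon_usage_index,
    gene_region_tallies,
    region_distribution,
    select_start_enriched,
    start_codon_fraction,
    start_context_test,
)
from seedribo.psite import PsiteRecord

from conftest import make_mrna


def _rec(tid, psite, frame, region, rid=""):
    return PsiteRecord(read_id=rid, transcript_id=tid, psite=psite,
                       length=28, frame=frame, region=region)


def _records_on(t, positions):
    return [
        _rec(t.transcript_id, p, (p - t.cds_start) % 3, t.region_of(p), rid=str(i))
        for i, p in enumerate(positions)
    ]


class TestRegionDistribution:
    def test_all_cds_gives_0_100_0(self):
        t = make_mrna()
        recs = _records_on(t, [t.cds_start, t.cds_start + 3])
        per = {("dry", 1): recs, ("dry", 2): recs}
        pct, _ = region_distribution(per)
        assert pct.loc[0, ["pct_utr5", "pct_cds", "pct_utr3"]].tolist() == [0, 100, 0]

    def test_percentages_sum_to_100_and_dry_differs(self, dry_library, ref):
        per = {("dry", 1): dry_library["records"]}
        pct, _ = region_distribution(per)
        assert pct[["pct_utr5", "pct_cds", "pct_utr3"]].sum(axis=1).tolist() == [
            pytest.approx(100.0)
        ]
        # dry preset plants the printed 92.3% CDS share
        n = len([r for r in dry_library["records"] if r.region is not None])
        se = 100 * np.sqrt(0.923 * 0.077 / n)
        assert pct.loc[0, "pct_cds"] == pytest.approx(92.3, abs=4 * se)

    def test_distinct_presets_yield_significant_welch_tests(self, ref):
        per = {}
        for stage, seeds in (("dry", (31, 32, 33)), ("hai6", (34, 35, 36))):
            preset = sim.PRESETS[stage].replace(contaminant_fracs={})
            for rep, s in enumerate(seeds, 1):
                _, truth = sim.simulate_footprints(ref, preset, 4000, seed=s,
                                                   add_adaptor=False)
                recs = [
                    _rec(r.transcript_id, r.psite, r.frame, r.region)
                    for r in truth.itertuples()
                ]
                per[(stage, rep)] = recs
        _, tests = region_distribution(per)
        assert tests.set_index("region").loc["cds", "significant"]

    def test_zero_mrna_psites_is_an_error(self):
        with pytest.raises(ValueError):
            region_distribution({("dry", 1): [_rec("L1", 3, None, None)]})


class TestCodonUsageIndex:
    def test_hand_computed_toy_indices(self):
        t = make_mrna("T1.1", utr5="", cds="ATGGGTGATTAA", utr3="AAAA")
        ref = ReferenceSet(transcripts={"T1.1": t})
        recs = _records_on(t, [0, 0, 3, 6])
        usage = codon_usage_index(recs, ref)
        idx = usage.table["index"]
        assert idx["AUG"] == pytest.approx(2.0)
        assert idx["GGU"] == pytest.approx(1.0)
        assert idx["GAU"] == pytest.approx(1.0)
        assert idx["UAA"] == pytest.approx(0.0)
        assert usage.start_count == 2

    def test_uniform_psites_give_index_one_everywhere(self, ref):
        recs = []
        for t in ref.mrnas():
            recs.extend(
                _records_on(t, range(t.cds_start, t.cds_end - 2, 3))
            )
        usage = codon_usage_index(recs, ref)
        present = usage.table.dropna(subset=["index"])
        assert np.allclose(present["index"], 1.0)

    def test_index_invariant_under_count_scaling(self, ref):
        t = ref.mrnas()[0]
        recs = _records_on(t, [t.cds_start, t.cds_start + 3, t.cds_start + 3])
        once = codon_usage_index(recs, ref, gene_set={t.gene_id})
        thrice = codon_usage_index(recs * 3, ref, gene_set={t.gene_id})
        pd.testing.assert_series_equal(once.table["index"], thrice.table["index"])

    def test_psite_fractions_and_frequencies_sum_to_one(self, dry_library, ref):
        usage = codon_usage_index(dry_library["records"], ref)
        assert usage.table["psite_frac"].sum() == pytest.approx(1.0)
        assert usage.table["codon_freq"].sum() == pytest.approx(1.0)


class TestStartCodonFraction:
    def test_all_start_psites_give_fraction_one(self, ref):
        t = ref.mrnas()[0]
        per = {("dry", 1): _records_on(t, [t.cds_start] * 5)}
        frac, _ = start_codon_fraction(per, ref)
        assert frac.loc[0, "frac_total"] == 1.0
        assert frac.loc[0, "frac_window"] == 1.0

    def test_dry_exceeds_imbibed_with_significant_welch_test(self, ref):
        per = {}
        for stage, seeds in (("dry", (41, 42, 43)), ("hai6", (44, 45, 46))):
            preset = sim.PRESETS[stage].replace(contaminant_fracs={})
            for rep, s in enumerate(seeds, 1):
                _, truth = sim.simulate_footprints(ref, preset, 4000, seed=s,
                                                   add_adaptor=False)
                per[(stage, rep)] = [
                    _rec(r.transcript_id, r.psite, r.frame, r.region)
                    for r in truth.itertuples()
                ]
        frac, tests = start_codon_fraction(per, ref)
        means = frac.groupby("stage")["frac_total"].mean()
        assert means["dry"] > means["hai6"]
        assert tests.loc[0, "p"] < 0.05


class TestSelectStartEnriched:
    @pytest.mark.parametrize(
        "at_start, total, expected",
        [
            (40, 200, True),   # 20% > 10% and 40 > 30
            (31, 310, False),  # exactly 10%: strict inequality fails
            (30, 100, False),  # 30 is not > 30
            (31, 309, True),
            (31, 310 * 10, False),
        ],
    )
    def test_thresholds_are_strict(self, at_start, total, expected):
        tallies = pd.DataFrame(
            {"psites_at_start": [at_start], "psites_cds_total": [total],
             "psites_utr5": [0], "psites_utr3": [0], "total_psites": [total]},
            index=["g"],
        )
        assert (("g" in select_start_enriched(tallies)) == expected)

    def test_zero_total_genes_are_skipped(self):
        tallies = pd.DataFrame(
            {"psites_at_start": [0], "psites_cds_total": [0],
             "psites_utr5": [0], "psites_utr3": [0], "total_psites": [0]},
            index=["g"],
        )
        assert select_start_enriched(tallies) == set()

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        at_start=hst.integers(min_value=0, max_value=500),
        rest=hst.integers(min_value=0, max_value=5000),
        extra=hst.integers(min_value=1, max_value=50),
    )
    def test_monotone_in_start_counts_at_fixed_total(self, at_start, rest, extra):
        # moving P sites from the CDS body onto the start codon (total fixed)
        # can never flip a passing gene to failing
        total = at_start + rest
        def passes(a):
            df = pd.DataFrame(
                {"psites_at_start": [a], "psites_cds_total": [total],
                 "psites_utr5": [0], "psites_utr3": [0],
                 "total_psites": [total]},
                index=["g"],
            )
            return "g" in select_start_enriched(df)

        if passes(at_start) and at_start + extra <= total:
            assert passes(at_start + extra)

    def test_tallies_match_truth_on_noiseless_library(self, dry_library, ref):
        tallies = gene_region_tallies(dry_library["records"], ref)
        truth = dry_library["truth"]
        mrna = truth[truth["category"] == "mRNA"].copy()
        gene_of = {t.transcript_id: t.gene_id for t in ref.mrnas()}
        mrna["gene"] = mrna["transcript_id"].map(gene_of)
        expected = mrna.groupby("gene").size()
        got = tallies["total_psites"]
        shared = expected.index.intersection(got.index)
        # identical up to reads dropped for lacking an offset entry
        assert (got[shared] <= expected[shared]).all()
        assert got[shared].sum() / expected.sum() > 0.99


class TestStartContextTest:
    def test_planted_minus3_bias_is_detected(self):
        ref_bg, truth_bg = sim.simulate_reference(
            n_mrna=1000, n_lncrna=0, n_contam=0, kozak_fraction=0.0, seed=51
        )
        ref_k, truth_k = sim.simulate_reference(
            n_mrna=176, n_lncrna=0, n_contam=0, kozak_fraction=1.0, seed=52
        )
        merged = dict(ref_bg.transcripts)
        for tid, t in ref_k.transcripts.items():
            merged["K" + tid] = type(t)(
                transcript_id="K" + tid, gene_id="K" + t.gene_id,
                biotype="mRNA", sequence=t.sequence,
                cds_start=t.cds_start, cds_end=t.cds_end,
            )
        ref = ReferenceSet(transcripts=merged)
        enriched = {"K" + g for g in truth_k["gene_id"]}
        background = set(truth_bg["gene_id"])
        table, consensus = start_context_test(enriched, background, ref)
        sig = set(table.index[table["significant"]])
        assert {-3, -2, 4} <= sig
        assert "AUG" in consensus
        assert table.loc[-3, "p"] < 1e-4

    def test_small_sets_raise(self, ref):
        genes = [t.gene_id for t in ref.mrnas()]
        with pytest.raises(ValueError, match=">= 20"):
            start_context_test(set(genes[:5]), set(genes[5:]), ref)
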