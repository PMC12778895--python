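import numpy as np
import pandas as pd
import pytest

from seedribo import simulate as sim
from seedribo.annotation import ReferenceSet
from seedribo.difftrans import CountMatrix
from seedribo.orfs import (
    annotate_uorfs,
    count_features,
    lncrna_translation,
    match_peptides,
    parse_uorf_gff,
    predict_orfs,
    uorf_morf_shift,
    uorfs_to_gff,
)
from seedribo.psite import PsiteRecord

from conftest import make_mrna

NONSTOP = "GCT"


def _orf(n_codons_total: int) -> str:
    # AUG + (n-2) body codons + stop; length = 3 * n_codons_total
    return "ATG" + NONSTOP * (n_codons_total - 2) + "TAA"


class TestPredictOrfs:
    def test_63bp_orf_is_kept_60bp_is_dropped(self):
        assert len(predict_orfs("CC" + _orf(21) + "GG")) == 1  # 63 bp
        assert predict_orfs("CC" + _orf(20) + "GG") == []      # 60 bp, not > 60

    def test_no_aug_means_no_orfs(self):
        assert predict_orfs("CCGGTTCCGGTT" * 20) == []

    def test_aug_without_inframe_stop_is_discarded(self):
        assert predict_orfs("ATG" + NONSTOP * 30) == []

    def test_every_qualifying_aug_yields_its_own_orf(self):
        seq = "ATGATG" + NONSTOP * 25 + "TAATAA"
        out = predict_orfs(seq)
        assert [o.start for o in out] == [0, 3]
        assert {o.frame for o in out} == {0}

    def test_peptide_and_coordinates(self):
        out = predict_orfs("GG" + _orf(21), offset=5, host_id="h")
        orf = out[0]
        assert (orf.start, orf.end) == (7, 70)
        assert orf.length_bp == 63
        assert orf.peptide == "M" + "A" * 19
        assert orf.host_id == "h"

    def test_agrees_with_three_frame_bruteforce_scan(self):
        rng = np.random.default_rng(71)
        nts = np.array(list("ACGT"))
        stops = {"TAA", "TAG", "TGA"}
        for _ in range(200):
            seq = "".join(nts[rng.integers(0, 4, 300)])
            expected = []
            for start in range(len(seq) - 2):
                if seq[start:start + 3] != "ATG":
                    continue
                for stop in range(start + 3, len(seq) - 2, 3):
                    if seq[stop:stop + 3] in stops:
                        if stop + 3 - start > 60:
                            expected.append((start, stop + 3))
                        break
            got = [(o.start, o.end) for o in predict_orfs(seq)]
            assert sorted(got) == sorted(expected)


class TestAnnotateUorfs:
    def test_planted_uorf_coordinates(self):
        utr = "GG" + _orf(21) + "C" * 15  # 80-nt UTR, ORF at offset 2
        t = make_mrna("TU.1", utr5=utr, cds="ATG" + "CAC" * 30 + "TGA",
                      utr3="T" * 30)
        ref = ReferenceSet(transcripts={"TU.1": t})
        uorfs = annotate_uorfs(ref)
        assert len(uorfs) == 1
        row = uorfs.iloc[0]
        assert (row["start"], row["end"]) == (2, 65)

    def test_orf_crossing_cds_start_is_excluded(self):
        # AUG near the UTR end whose only in-frame stop sits inside the CDS
        utr = "C" * 60 + "ATG" + NONSTOP * 2  # no stop before cds_start
        t = make_mrna("TX.1", utr5=utr, cds="ATG" + NONSTOP * 20 + "TAA" * 2,
                      utr3="T" * 30)
        ref = ReferenceSet(transcripts={"TX.1": t})
        assert len(annotate_uorfs(ref)) == 0

    def test_no_utr_means_no_uorfs(self):
        t = make_mrna("TZ.1", utr5="", cds=_orf(25), utr3="T" * 10)
        assert len(annotate_uorfs(ReferenceSet(transcripts={"TZ.1": t}))) == 0

    def test_gff_roundtrip_preserves_intervals(self, ref):
        uorfs = annotate_uorfs(ref)
        back = parse_uorf_gff(uorfs_to_gff(uorfs))
        pd.testing.assert_frame_equal(
            back[["feature_id", "start", "end"]],
            uorfs[["feature_id", "start", "end"]],
        )

    def test_planted_uorfs_are_found(self, sim_reference):
        ref, truth = sim_reference
        planted = truth[(truth["biotype"] == "mRNA") & (truth["orf_start"] >= 0)]
        uorfs = annotate_uorfs(ref)
        for row in planted.itertuples():
            hit = uorfs[
                (uorfs["transcript_id"] == row.transcript_id)
                & (uorfs["start"] == row.orf_start)
                & (uorfs["end"] == row.orf_end)
            ]
            assert len(hit) == 1


class TestCountFeatures:
    def test_psites_increment_the_containing_feature_only(self):
        feats = pd.DataFrame(
            [{"feature_id": "u1", "transcript_id": "T", "start": 5, "end": 20},
             {"feature_id": "u2", "transcript_id": "T", "start": 30, "end": 40}]
        )
        recs = [
            PsiteRecord("a", "T", 5, 28, 0, "utr5"),   # u1 start
            PsiteRecord("b", "T", 25, 28, 0, "utr5"),  # between features
            PsiteRecord("c", "T", 39, 28, 0, "utr5"),  # u2
            PsiteRecord("d", "OTHER", 7, 28, 0, "utr5"),
        ]
        counts = count_features(recs, feats)
        assert counts.to_dict() == {"u1": 1, "u2": 1}
        assert counts.sum() <= len(recs)


def _nb_counts(rng, ids, base, fold_by_id, stages=("dry", "hai6"), reps=3,
               disp=0.05):
    meta = pd.DataFrame(
        [{"sample": f"r_{s}_{r}", "stage": s, "replicate": r, "assay": "ribo"}
         for s in stages for r in range(1, reps + 1)]
    ).set_index("sample")
    cols = {}
    for s in stages:
        for r in range(1, reps + 1):
            mult = np.array([fold_by_id.get(i, 1.0) if s == stages[1] else 1.0
                             for i in ids])
            rr = 1 / disp
            mu = base * mult
            cols[f"r_{s}_{r}"] = rng.negative_binomial(rr, rr / (rr + mu))
    return CountMatrix(counts=pd.DataFrame(cols, index=ids), samples=meta)


class TestUorfMorfShift:
    def test_same_direction_shifts_are_never_flagged(self):
        rng = np.random.default_rng(72)
        genes = [f"g{i}" for i in range(12)]
        uorf_ids = [f"{g}.u" for g in genes]
        up = {x: 4.0 for x in genes[:6]} | {f"{g}.u": 4.0 for g in genes[:6]}
        uorf_cm = _nb_counts(rng, uorf_ids, 300.0, up)
        cds_cm = _nb_counts(rng, genes, 800.0, up)
        res = uorf_morf_shift(
            uorf_cm, cds_cm, ("dry", "hai6"),
            pd.Series(66, index=uorf_ids), pd.Series(900, index=genes),
            pd.Series(genes, index=uorf_ids),
        )
        assert not res["opposite"].any()

    def test_opposite_shifts_are_flagged(self):
        rng = np.random.default_rng(73)
        genes = [f"g{i}" for i in range(12)]
        uorf_ids = [f"{g}.u" for g in genes]
        uorf_cm = _nb_counts(rng, uorf_ids, 300.0,
                             {f"{g}.u": 4.0 for g in genes[:3]})
        cds_cm = _nb_counts(rng, genes, 800.0, {g: 0.25 for g in genes[:3]})
        res = uorf_morf_shift(
            uorf_cm, cds_cm, ("dry", "hai6"),
            pd.Series(66, index=uorf_ids), pd.Series(900, index=genes),
            pd.Series(genes, index=uorf_ids),
        )
        assert res.loc[genes[:3], "opposite"].all()
        # a stray null flag is possible at the nominal FDR; no more than one
        assert res.loc[genes[3:], "opposite"].sum() <= 1

    def test_low_rpkm_genes_are_filtered_out(self):
        rng = np.random.default_rng(74)
        genes = ["g0", "g1"]
        uorf_ids = ["g0.u", "g1.u"]
        uorf_cm = _nb_counts(rng, uorf_ids, 300.0, {})
        cds_cm = _nb_counts(rng, genes, 800.0, {})
        # huge nominal length sends g0's rpkm below the threshold
        lengths = pd.Series({"g0.u": 66 * 10**9, "g1.u": 66})
        res = uorf_morf_shift(
            uorf_cm, cds_cm, ("dry", "hai6"),
            lengths, pd.Series(900, index=genes),
            pd.Series(genes, index=uorf_ids),
        )
        assert "g0" not in res.index and "g1" in res.index


class TestLncrnaTranslation:
    def test_planted_shift_on_orf_bearing_lncrna_is_regulated(self):
        ref, truth = sim.simulate_reference(n_mrna=40, n_lncrna=10, n_contam=0,
                                            seed=75)
        lnc = truth[truth["biotype"] == "lncRNA"]
        target = lnc[lnc["orf_start"] >= 0].iloc[0]["transcript_id"]
        ribo, total, _ = sim.simulate_expression_counts(
            ref, design=[("dry", 3), ("hai6", 3)],
            te_shift_spec={target: 2.5}, seed=76, dispersion_range=(0.05, 0.05),
        )
        lengths = pd.Series(
            {t.transcript_id: t.length for t in ref.by_category("lncRNA")}
        )
        orf_bearing = set(lnc[lnc["orf_start"] >= 0]["transcript_id"])
        res = lncrna_translation(ribo, total, ("dry", "hai6"), lengths,
                                 orf_bearing)
        if target in res.index:
            assert res.loc[target, "regulated"]
            assert res.loc[target, "has_orf"]
        regulated_null = res.drop(index=target, errors="ignore")["regulated"]
        assert regulated_null.mean() <= 0.25


class TestMatchPeptides:
    def test_containment_is_exact(self):
        predicted = pd.Series({"orf1": "MMKLVTTRQSTW"})
        observed = pd.DataFrame(
            {"peptide": ["MKLVTTR", "MKLVTSR", "MKLVT"],
             "stage": ["dry", "dry", "dry"]}
        )
        out = match_peptides(predicted, observed)
        assert out["peptide"].tolist() == ["MKLVTTR"]
        assert out["orf_id"].tolist() == ["orf1"]

    def test_planted_orf_peptides_are_fully_recovered(self, sim_reference):
        ref, truth = sim_reference
        from seedribo.orfs import predict_orfs as po

        predicted = {}
        for t in ref.by_category("lncRNA"):
            for i, orf in enumerate(po(t.sequence)):
                predicted[f"{t.transcript_id}.orf{i}"] = orf.peptide
        predicted = pd.Series(predicted)
        observed = pd.DataFrame(
            {"peptide": [p[:9] for p in predicted.values if len(p) >= 9],
             "stage": "dry"}
        )
        out = match_peptides(predicted, observed)
        assert set(observed["peptide"]) == set(out["peptide"])
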