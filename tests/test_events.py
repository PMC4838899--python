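import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from otomics import (
    CohortConfig,
    GNLTable,
    MYC_REGION_HG19,
    OmicsMatrix,
    ValidationError,
    call_arm_status,
    call_cpg_hypermethylation,
    call_cpg_hypomethylation,
    call_gene_event,
    cimp_status,
    codel_from_expression,
    generate_cohort,
)

MYC = MYC_REGION_HG19


def seg_table(rows):
    return GNLTable(
        "segment",
        segments=pd.DataFrame(rows, columns=["sample", "chrom", "start", "end", "gnl"]),
    )


class TestGeneEvent:
    def test_full_gain_coverage_is_true(self):
        gnl = seg_table([("T1", "8", 1, 146_364_022, 1)])
        assert call_gene_event(gnl, MYC, "gain")["T1"] == True

    def test_partial_sign_is_false(self):
        mid = (MYC[1] + MYC[2]) // 2
        gnl = seg_table(
            [("T1", "8", 1, mid, 1), ("T1", "8", mid + 1, 146_364_022, 0)]
        )
        assert call_gene_event(gnl, MYC, "gain")["T1"] == False

    def test_uncovered_region_is_na(self):
        gnl = seg_table([("T1", "8", 1, 1_000_000, 1)])
        assert pd.isna(call_gene_event(gnl, MYC, "gain")["T1"])

    def test_loss_call_on_max_region(self):
        from otomics import MAX_REGION_HG19

        gnl = seg_table([("T1", "14", 1, 107_349_540, -1)])
        assert call_gene_event(gnl, MAX_REGION_HG19, "loss")["T1"] == True

    def test_monotone_under_segment_flips(self):
        # flipping any overlapping segment away from the target sign can
        # only turn a True call into False, never the reverse
        rng = np.random.default_rng(0)
        mid = (MYC[1] + MYC[2]) // 2
        rows = [("T1", "8", 1, mid, 1), ("T1", "8", mid + 1, 146_364_022, 1)]
        base = call_gene_event(seg_table(rows), MYC, "gain")["T1"]
        assert base == True
        for i in range(2):
            flipped = [list(r) for r in rows]
            flipped[i][4] = int(rng.choice([-1, 0, 2 if i else 0]))
            new = call_gene_event(seg_table(flipped), MYC, "gain")["T1"]
            if flipped[i][4] not in (1, 2):
                assert new == False

    def test_gene_mode_calls(self):
        genes = pd.DataFrame({"T1": [1, -1], "T2": [0, np.nan]}, index=["MYC", "MAX"])
        gnl = GNLTable("gene", genes=genes)
        gains = call_gene_event(gnl, "MYC", "gain")
        losses = call_gene_event(gnl, "MAX", "loss")
        assert gains["T1"] == True and gains["T2"] == False
        assert losses["T1"] == True and pd.isna(losses["T2"])


class TestArmStatus:
    def test_whole_arm_loss(self):
        gnl = seg_table([("T1", "1", 1, 121_535_434, -1)])
        assert call_arm_status(gnl, "1p")["T1"] == -1

    def test_sixty_percent_below_threshold_is_neutral(self):
        split = int(121_535_434 * 0.6)
        gnl = seg_table(
            [("T1", "1", 1, split, -1), ("T1", "1", split + 1, 121_535_434, 0)]
        )
        assert call_arm_status(gnl, "1p")["T1"] == 0

    def test_low_coverage_is_na(self):
        gnl = seg_table([("T1", "1", 1, 10_000_000, -1)])
        assert pd.isna(call_arm_status(gnl, "1p")["T1"])

    def test_codeleted_generator_samples_lose_both_arms(self, clean_cohort):
        c = clean_cohort
        codel = c.truth.index[c.truth["codel"].astype(bool)][:10]
        for arm in ("1p", "19q"):
            calls = call_arm_status(c.gnl, arm)
            assert (calls.loc[codel] == -1).all()


class TestCodelFromExpression:
    def test_exact_split_on_hand_scores(self):
        # u values cluster as (-.4,-.38,-.35) vs (0,.02,.05): minimal
        # within-class variance splits between them; low side = co-deleted
        u = [-0.4, -0.38, -0.35, 0.0, 0.02, 0.05]
        values, annots = [], []
        rng = np.random.default_rng(1)
        genes_1p = [f"p{i}" for i in range(5)]
        genes_19q = [f"q{i}" for i in range(5)]
        mat = pd.DataFrame(
            np.array(u)[None, :].repeat(10, axis=0),
            index=genes_1p + genes_19q,
            columns=[f"s{i}" for i in range(6)],
        )
        annot = pd.DataFrame(
            {"arm": ["1p"] * 5 + ["19q"] * 5}, index=mat.index
        )
        m = OmicsMatrix(mat, "mrna", annot)
        codel, scores = codel_from_expression(m)
        assert codel[:3].all() and not codel[3:].any()

    def test_constant_samples_give_no_call(self):
        mat = pd.DataFrame(
            np.ones((10, 6)), index=[f"g{i}" for i in range(10)],
            columns=[f"s{i}" for i in range(6)],
        )
        annot = pd.DataFrame({"arm": ["1p"] * 5 + ["19q"] * 5}, index=mat.index)
        with pytest.warns(UserWarning, match="degenerate"):
            codel, _ = codel_from_expression(OmicsMatrix(mat, "mrna", annot))
        assert codel.isna().all()

    def test_invariant_to_constant_offsets(self, rng):
        # double-centring cancels both a constant added to any sample's
        # whole column and a constant added to any gene's whole row
        cfg = CohortConfig(
            subtype_names=("A", "B"), n_per_subtype=(20, 20),
            codel_subtypes=("A",), aggressive_subtype="A", idhwt_subtypes=(),
            n_normal_controls=0, n_contaminated=0, noise_sd=0.2,
            missing_fraction={"mrna": 0, "mirna": 0, "methylation": 0}, seed=3,
        )
        c = generate_cohort(cfg)
        codel1, _ = codel_from_expression(c.mrna)
        col_shift = c.mrna.values.add(
            pd.Series(rng.normal(0, 5, size=c.mrna.values.shape[1]),
                      index=c.mrna.values.columns), axis=1,
        )
        codel2, _ = codel_from_expression(
            OmicsMatrix(col_shift, "mrna", c.mrna.feature_annot)
        )
        pd.testing.assert_series_equal(codel1, codel2)
        row_shift = c.mrna.values.add(
            pd.Series(rng.normal(0, 5, size=c.mrna.values.shape[0]),
                      index=c.mrna.values.index), axis=0,
        )
        codel3, _ = codel_from_expression(
            OmicsMatrix(row_shift, "mrna", c.mrna.feature_annot)
        )
        pd.testing.assert_series_equal(codel1, codel3)


class TestCpgCalls:
    def _meth(self, betas, cpg="cg00163372"):
        mat = pd.DataFrame(
            [betas], index=[cpg], columns=[f"s{i}" for i in range(len(betas))]
        )
        return OmicsMatrix(mat, "methylation")

    def test_hypomethylation_strict_inequality(self):
        m = self._meth([0.49, 0.5, np.nan])
        calls = call_cpg_hypomethylation(m)
        assert calls["s0"] == True
        assert calls["s1"] == False  # exactly at threshold: not hypomethylated
        assert pd.isna(calls["s2"])

    def test_missing_cpg_error_names_id(self):
        m = self._meth([0.4], cpg="cgOTHER")
        with pytest.raises(ValidationError, match="cg00163372"):
            call_cpg_hypomethylation(m)

    def test_hypermethylation_mean_plus_two_sd(self):
        betas = [0.1] * 9 + [0.9]
        m = self._meth(betas, cpg="cg22879515")
        calls, thr = call_cpg_hypermethylation(m)
        assert thr == pytest.approx(0.18 + 2 * 0.25298221, abs=1e-6)
        assert calls["s9"] == True
        assert not calls.drop("s9").astype(bool).any()

    def test_constant_betas_call_nothing(self):
        m = self._meth([0.4] * 12, cpg="cg22879515")
        with pytest.warns(UserWarning, match="zero SD"):
            calls, _ = call_cpg_hypermethylation(m)
        assert not calls.astype(bool).any()

    def test_generator_event_recovery(self, default_cohort):
        c = default_cohort
        hypo = call_cpg_hypomethylation(c.methylation).dropna()
        truth = c.truth.loc[hypo.index]
        assert (hypo == truth["myc_hypometh"]).mean() >= 0.95
        hyper, _ = call_cpg_hypermethylation(c.methylation)
        hyper = hyper.dropna()
        truth = c.truth.loc[hyper.index]
        planted = truth["mir34_hypermeth"].astype(bool)
        assert (hyper[planted] == True).mean() >= 0.9  # noqa: E712
        assert (hyper[~planted] == False).mean() >= 0.95  # noqa: E712


class TestCimp:
    def test_planted_island_offset_recovered(self, clean_cohort):
        c = clean_cohort
        calls = cimp_status(c.methylation, seed=1)
        truth = c.truth.loc[calls.index, "cimp"].astype(bool)
        assert adjusted_rand_score(truth, calls) >= 0.95

    def test_polarity_defined_by_mean_beta_not_label(self, clean_cohort):
        c = clean_cohort
        a = cimp_status(c.methylation, seed=1)
        b = cimp_status(c.methylation, seed=99)
        # different resampling seeds may permute class ids but never the
        # positive/negative polarity
        assert (a == b).mean() >= 0.95

    def test_missing_island_annotation_rejected(self, clean_cohort):
        m = OmicsMatrix(clean_cohort.methylation.values, "methylation")
        with pytest.raises(ValidationError):
            cimp_status(m)
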