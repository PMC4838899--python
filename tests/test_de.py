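from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest, ttest_ind

from otomics import (
    GeneSet,
    ValidationError,
    hypergeom_enrich,
    moderated_t,
    myc_activity_score,
    signature_top_n,
)

from conftest import make_matrix


def simulate_genes(rng, d0=4.0, s02=0.25, n_genes=2000, n1=8, n0=8, shift=0.0):
    sigma2 = s02 * d0 / rng.chisquare(d0, n_genes)
    x = rng.normal(0.0, np.sqrt(sigma2)[:, None], (n_genes, n1 + n0))
    x[:, :n1] += shift
    mat = make_matrix(x)
    group = pd.Series([True] * n1 + [False] * n0, index=mat.columns)
    return mat, group


class TestModeratedT:
    def test_zero_prior_df_reduces_to_student_t(self, rng):
        mat, group = simulate_genes(rng, n_genes=300)
        res = moderated_t(mat, group, prior_df=0.0)
        ref = ttest_ind(mat.loc[:, group], mat.loc[:, ~group], axis=1, equal_var=True)
        assert np.nanmax(np.abs(res.table["t"] - ref.statistic)) < 1e-10
        assert np.nanmax(np.abs(res.table["p"] - ref.pvalue)) < 1e-10

    def test_infinite_prior_df_pins_variance(self, rng):
        mat, group = simulate_genes(rng, n_genes=200)
        res = moderated_t(mat, group, prior_df=np.inf, prior_var=1.0)
        n1 = n0 = 8
        expected = res.table["lfc"] / np.sqrt(1 / n1 + 1 / n0)
        assert np.allclose(res.table["t"], expected)

    def test_prior_recovery_from_simulated_variances(self):
        rng = np.random.default_rng(5)
        mat, group = simulate_genes(rng, d0=4.0, s02=0.25, n_genes=5000)
        res = moderated_t(mat, group)
        assert 2.0 <= res.d0 <= 8.0
        assert abs(res.s02 - 0.25) / 0.25 <= 0.2

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(6)
        mat, group = simulate_genes(rng, n_genes=5000)
        res = moderated_t(mat, group)
        assert kstest(res.table["p"].dropna(), "uniform").pvalue > 0.01

    def test_t_sign_matches_lfc_sign(self, rng):
        mat, group = simulate_genes(rng, n_genes=500, shift=0.5)
        tab = moderated_t(mat, group).table.dropna()
        assert (np.sign(tab["t"]) == np.sign(tab["lfc"])).all()

    def test_zero_variance_feature_gets_na(self):
        mat = make_matrix([[1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0]])
        group = pd.Series([True, True, False, False], index=mat.columns)
        res = moderated_t(mat, group)
        assert np.isnan(res.table.loc["g0", "p"])

    def test_bh_adjustment_monotone(self, rng):
        mat, group = simulate_genes(rng, n_genes=300, shift=1.0)
        tab = moderated_t(mat, group, adjust=True).table.dropna()
        assert (tab["padj"] >= tab["p"] - 1e-12).all()


class TestSignatureTopN:
    def _de(self, lfc, p):
        from otomics.de import DEResult

        table = pd.DataFrame(
            {"lfc": lfc, "p": p, "t": lfc, "df": 10.0},
            index=[f"g{i}" for i in range(len(lfc))],
        )
        return DEResult(table, d0=1.0, s02=1.0)

    def test_ranked_by_fold_change_among_significant(self):
        de = self._de([2.0, 1.5, 3.0], [0.01, 0.01, 0.01])
        assert signature_top_n(de, n=2) == ["g2", "g0"]

    def test_non_significant_high_fold_change_excluded(self):
        de = self._de([5.0, 1.0], [0.2, 0.01])
        assert signature_top_n(de, n=2) == ["g1"]

    def test_down_regulated_excluded(self):
        de = self._de([-3.0, 1.0], [0.001, 0.01])
        assert signature_top_n(de, n=5) == ["g1"]

    def test_none_significant_warns_empty(self):
        de = self._de([1.0, 2.0], [0.5, 0.9])
        with pytest.warns(UserWarning):
            assert signature_top_n(de) == []


class TestHypergeomEnrich:
    def test_complete_overlap_closed_form(self):
        from math import comb

        universe = [f"g{i}" for i in range(100)]
        sig = universe[:10]
        gs = GeneSet("set", tuple(universe[:10]))
        p, k = hypergeom_enrich(sig, gs, universe)
        assert k == 10
        assert p == pytest.approx(1 / comb(100, 10), rel=1e-9)

    def test_zero_overlap_gives_p_one(self):
        universe = [f"g{i}" for i in range(50)]
        p, k = hypergeom_enrich(universe[:5], GeneSet("s", tuple(universe[40:])), universe)
        assert k == 0 and p == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration(self):
        # brute-force over all signature draws for a small universe
        from math import comb

        universe = [f"g{i}" for i in range(12)]
        members = set(universe[:5])
        n_sig = 4
        for observed in universe_draws_overlap_counts(universe, members, n_sig):
            p, _ = hypergeom_enrich(observed["sig"], GeneSet("s", tuple(members)), universe)
            count_ge = sum(
                1
                for draw in combinations(universe, n_sig)
                if len(set(draw) & members) >= observed["k"]
            )
            assert p == pytest.approx(count_ge / comb(12, n_sig), rel=1e-9)

    def test_signature_outside_universe_rejected(self):
        with pytest.raises(ValidationError):
            hypergeom_enrich(["x"], GeneSet("s", ("a",)), ["a", "b"])


def universe_draws_overlap_counts(universe, members, n_sig):
    # a few representative signatures with different overlaps
    non = [g for g in universe if g not in members]
    mem = sorted(members)
    yield {"sig": mem[:4], "k": 4}
    yield {"sig": mem[:2] + non[:2], "k": 2}
    yield {"sig": non[:4], "k": 0}


class TestMycActivityScore:
    def test_mean_of_centred_targets(self):
        mat = make_matrix([[2.0, 0.0], [4.0, 2.0], [5.0, 5.0]])
        gs = GeneSet("targets", ("g0", "g1"))
        scores, missing = myc_activity_score(mat, gs)
        # centred g0 -> (1, -1); g1 -> (1, -1); mean -> (1, -1)
        assert scores.tolist() == [1.0, -1.0]
        assert missing == []

    def test_cohort_mean_of_scores_is_zero(self, rng):
        mat = make_matrix(rng.normal(size=(30, 12)))
        gs = GeneSet("targets", tuple(f"g{i}" for i in range(8)))
        scores, _ = myc_activity_score(mat, gs)
        assert abs(scores.mean()) < 1e-12

    def test_missing_targets_reported(self, rng):
        mat = make_matrix(rng.normal(size=(5, 4)))
        gs = GeneSet("targets", ("g0", "nope"))
        _, missing = myc_activity_score(mat, gs)
        assert missing == ["nope"]

    def test_no_targets_present_rejected(self, rng):
        mat = make_matrix(rng.normal(size=(3, 3)))
        with pytest.raises(ValidationError):
            myc_activity_score(mat, GeneSet("targets", ("zz",)))

    def test_planted_target_shift_detected_across_seeds(self):
        # the aggressive subtype carries MYC events that shift the target
        # genes; the score separates it from the rest in >= 9/10 seeds
        from otomics import CohortConfig, generate_cohort

        hits = 0
        for seed in range(10):
            cfg = CohortConfig(
                subtype_names=("O1", "O2"), n_per_subtype=(30, 30),
                codel_subtypes=("O1", "O2"), aggressive_subtype="O1",
                idhwt_subtypes=(), n_normal_controls=0, n_contaminated=0,
                aggressive_event_probs=(0.0, 0.0, 1.0, 0.0),
                background_event_prob=0.0,
                missing_fraction={"mrna": 0, "mirna": 0, "methylation": 0},
                seed=50 + seed,
            )
            c = generate_cohort(cfg)
            gs = GeneSet("targets", tuple(c.myc_target_genes))
            scores, _ = myc_activity_score(c.mrna, gs)
            o1 = c.truth["subtype"] == "O1"
            p = ttest_ind(scores[o1.to_numpy()], scores[~o1.to_numpy()]).pvalue
            hits += p < 0.01
        assert hits >= 9
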