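"""Detection-call filtering, the SAM statistic, permutation FDR, set algebra."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from telostress.expression_de import (
    ExpressionBundle,
    choose_s0,
    extract_de,
    filter_absent,
    sam_d,
    sam_fdr,
    stress_specific_sets,
)
from telostress.synthetic_data import gen_expression


def _bundle_from(matrix, calls, labels):
    samples = matrix.columns
    return ExpressionBundle(
        matrix=matrix,
        calls=calls,
        groups=pd.Series(labels, index=samples, name="condition"),
    )


def _random_two_group(rng, n_genes=50, n1=4, n2=3):
    samples = [f"c{i}" for i in range(n1)] + [f"s{i}" for i in range(n2)]
    matrix = pd.DataFrame(
        rng.normal(size=(n_genes, n1 + n2)),
        index=[f"g{i}" for i in range(n_genes)],
        columns=samples,
    )
    calls = pd.DataFrame("P", index=matrix.index, columns=samples)
    return _bundle_from(matrix, calls, ["control"] * n1 + ["stress"] * n2)


class TestFilterAbsent:
    @pytest.mark.parametrize("n_absent,kept", [(4, False), (3, True), (0, True)])
    def test_majority_absent_rule_on_seven_samples(self, n_absent, kept, rng):
        bundle = _random_two_group(rng, n_genes=5)
        calls = bundle.calls.copy()
        calls.iloc[0, :n_absent] = "A"
        bundle = _bundle_from(bundle.matrix, calls, bundle.groups.values)
        out = filter_absent(bundle)
        assert (bundle.matrix.index[0] in out.matrix.index) is kept

    def test_all_present_is_identity_and_idempotent(self, rng):
        bundle = _random_two_group(rng)
        once = filter_absent(bundle)
        twice = filter_absent(once)
        pd.testing.assert_frame_equal(bundle.matrix, once.matrix)
        pd.testing.assert_frame_equal(once.matrix, twice.matrix)

    def test_marginal_counts_as_present(self, rng):
        bundle = _random_two_group(rng, n_genes=3)
        calls = bundle.calls.copy()
        calls.iloc[1, :] = "M"
        out = filter_absent(_bundle_from(bundle.matrix, calls, bundle.groups.values))
        assert bundle.matrix.index[1] in out.matrix.index

    def test_empty_result_warns(self, rng):
        bundle = _random_two_group(rng, n_genes=3)
        calls = pd.DataFrame("A", index=bundle.matrix.index, columns=bundle.matrix.columns)
        with pytest.warns(UserWarning, match="every gene"):
            out = filter_absent(_bundle_from(bundle.matrix, calls, bundle.groups.values))
        assert len(out.matrix) == 0


class TestSamStatistic:
    def test_equal_group_means_give_zero(self):
        matrix = pd.DataFrame(
            [[1.0, 2.0, 3.0, 2.0, 1.0, 2.0, 3.0]],
            index=["g0"],
            columns=[f"x{i}" for i in range(7)],
        )
        labels = ["control"] * 4 + ["stress"] * 3
        d = sam_d(matrix, pd.Series(labels, index=matrix.columns), s0=0.5)
        # control mean (1+2+3+2)/4 = 2, stress mean (1+2+3)/3 = 2
        assert d.iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_s0_zero_is_pooled_t(self, rng):
        # independent oracle: scipy's classical pooled-variance two-sample t
        bundle = _random_two_group(rng, n_genes=200)
        d = sam_d(bundle.matrix, bundle.groups, s0=0.0,
                  stress="stress", control="control")
        xs = bundle.matrix.loc[:, bundle.groups == "stress"].to_numpy()
        xc = bundle.matrix.loc[:, bundle.groups == "control"].to_numpy()
        t, _ = stats.ttest_ind(xs, xc, axis=1, equal_var=True)
        np.testing.assert_allclose(d.to_numpy(), t, atol=1e-10)

    def test_larger_s0_never_increases_magnitude(self, rng):
        bundle = _random_two_group(rng, n_genes=100)
        d1 = sam_d(bundle.matrix, bundle.groups, s0=0.3)
        d2 = sam_d(bundle.matrix, bundle.groups, s0=0.6)
        assert np.all(np.abs(d2) <= np.abs(d1) + 1e-12)

    def test_zero_variance_gene_rejected_without_s0(self, rng):
        bundle = _random_two_group(rng, n_genes=5)
        matrix = bundle.matrix.copy()
        matrix.iloc[2] = 7.0
        with pytest.raises(ValueError, match="zero-variance"):
            sam_d(matrix, bundle.groups, s0=0.0)
        d = sam_d(matrix, bundle.groups, s0=0.1)
        assert d.iloc[2] == pytest.approx(0.0)


class TestChooseS0:
    def test_scale_equivariance_and_determinism(self, rng):
        bundle = _random_two_group(rng, n_genes=400)
        s0 = choose_s0(bundle.matrix, bundle.groups)
        s0_again = choose_s0(bundle.matrix, bundle.groups)
        s0_scaled = choose_s0(bundle.matrix * 3.0, bundle.groups)
        assert s0 == s0_again
        assert s0_scaled == pytest.approx(3.0 * s0, rel=1e-9)

    def test_homoscedastic_null_gives_moderate_s0(self, rng):
        bundle = _random_two_group(rng, n_genes=1000)
        s0 = choose_s0(bundle.matrix, bundle.groups)
        s = np.median(
            np.abs(bundle.matrix.sub(bundle.matrix.mean(axis=1), axis=0)).to_numpy()
        )
        assert 0.0 <= s0 <= 20 * s  # bounded; no runaway fudge factor

    def test_degenerate_equal_s_warns_zero(self):
        matrix = pd.DataFrame(
            np.tile([[0.0, 1.0, 0.0, 1.0, 0.0, 1.0, 1.0]], (120, 1)),
            index=[f"g{i}" for i in range(120)],
            columns=[f"x{i}" for i in range(7)],
        )
        labels = pd.Series(["a"] * 4 + ["b"] * 3, index=matrix.columns)
        with pytest.warns(UserWarning, match="s0 set to 0"):
            assert choose_s0(matrix, labels) == 0.0


class TestSamFdr:
    def test_enumerates_all_assignments_for_4v3(self, planted_bundle):
        bundle, _ = planted_bundle
        sub = filter_absent(bundle).subset(["control", "ethanol"])
        with pytest.warns(UserWarning, match="35 distinct"):
            res = sam_fdr(sub, n_perm=200, seed=0, stress="ethanol")
        assert res.n_perm == 35
        assert res.q.between(0, 1).all()

    def test_null_data_yields_no_significant_genes(self):
        # median estimator: typical null run finds nothing, but the median
        # false-count is known to be anticonservative for 1-2 extreme genes;
        # the q90 variant controls the any-hit rate tightly
        n_hits, n_hits_q90 = [], []
        for seed in range(10):
            bundle, _ = gen_expression(
                n_genes=1000, stresses=["ethanol"], de_fraction=0.0, seed=seed
            )
            sub = filter_absent(bundle).subset(["control", "ethanol"])
            n_hits.append(len(sam_fdr(sub, n_perm=200, seed=seed,
                                      stress="ethanol").significant))
            n_hits_q90.append(len(sam_fdr(sub, n_perm=200, seed=seed,
                                          stress="ethanol",
                                          estimator="q90").significant))
        assert np.median(n_hits) == 0
        assert max(n_hits) <= 5  # never more than a handful of flukes
        assert sum(h > 0 for h in n_hits_q90) <= 2

    def test_planted_genes_rank_above_null_and_are_recovered(self, planted_bundle):
        bundle, truth = planted_bundle
        filtered = filter_absent(bundle)
        res = sam_fdr(filtered.subset(["control", "ethanol"]), n_perm=200,
                      seed=0, stress="ethanol")
        planted = truth.de_genes_per_stress["ethanol"] & set(filtered.matrix.index)
        abs_d = res.d.abs()
        assert abs_d[list(planted)].mean() > 3 * abs_d.drop(list(planted)).mean()
        recall = len(set(res.significant) & planted) / len(planted)
        assert recall >= 0.4
        # every significant call is monotone-consistent: nothing below the
        # weakest significant |d| is called significant
        if res.significant:
            dmin = abs_d[list(res.significant)].min()
            assert (res.q[abs_d >= dmin] < res.fdr_threshold).all()

    def test_recall_increases_with_effect_size(self):
        recalls = {}
        for effect in (1.5, 2.5):
            bundle, truth = gen_expression(
                n_genes=500, stresses=["ethanol"], de_fraction=0.05,
                effect=effect, sigma=0.5, seed=21,
            )
            filtered = filter_absent(bundle)
            res = sam_fdr(filtered.subset(["control", "ethanol"]), n_perm=200,
                          seed=21, stress="ethanol")
            planted = truth.de_genes_per_stress["ethanol"] & set(filtered.matrix.index)
            recalls[effect] = len(set(res.significant) & planted) / len(planted)
        assert recalls[2.5] >= recalls[1.5]
        assert recalls[2.5] >= 0.9

    def test_determinism_under_seed(self, planted_bundle):
        bundle, _ = planted_bundle
        sub = filter_absent(bundle).subset(["control", "ethanol"])
        r1 = sam_fdr(sub, n_perm=200, seed=5, stress="ethanol")
        r2 = sam_fdr(sub, n_perm=200, seed=5, stress="ethanol")
        pd.testing.assert_series_equal(r1.q, r2.q)
        assert r1.significant == r2.significant


class TestStressSpecificSets:
    def test_set_difference_example(self):
        sets = stress_specific_sets(
            {"ethanol": {"g1", "g2"}, "caffeine": {"g2", "g3"}}
        )
        assert sets.specific["ethanol"] == {"g1"}
        assert sets.specific["caffeine"] == {"g3"}

    def test_identical_sets_make_empty_specifics(self):
        sets = stress_specific_sets({"a": {"g1"}, "b": {"g1"}, "c": {"g1"}})
        assert all(not s for s in sets.specific.values())

    def test_disjoint_sets_are_their_own_specifics(self):
        de = {"a": {"g1"}, "b": {"g2"}, "c": {"g3"}, "d": {"g4"}}
        sets = stress_specific_sets(de)
        assert sets.specific == de

    def test_specific_sets_pairwise_disjoint_on_random_inputs(self, rng):
        genes = [f"g{i}" for i in range(60)]
        de = {
            s: set(rng.choice(genes, size=rng.integers(5, 30), replace=False))
            for s in ("w", "x", "y", "z")
        }
        sets = stress_specific_sets(de)
        names = list(sets.specific)
        for i, s in enumerate(names):
            assert sets.specific[s] <= de[s]
            for t in names[i + 1:]:
                assert not (sets.specific[s] & sets.specific[t])

    def test_direction_groups(self):
        de = {"ethanol": {"g1", "g5"}, "caffeine": {"g2", "g5"}, "temp37": {"g2", "g9"},
              "h2o2": {"g7"}}
        sets = stress_specific_sets(
            de,
            {"elongating": ["ethanol"], "shortening": ["caffeine", "temp37"],
             "neutral": ["h2o2"]},
        )
        # DE under every shortening stress and no stress outside the group
        assert sets.direction_specific["shortening"] == {"g2"}
        assert sets.direction_specific["elongating"] == {"g1"}
        with pytest.raises(ValueError, match="unknown stresses"):
            stress_specific_sets(de, {"elongating": ["bogus"]})


def test_extract_de_runs_per_stress(planted_bundle):
    bundle, truth = planted_bundle
    results = extract_de(bundle, control="control", n_perm=200, seed=0)
    assert set(results) == {"ethanol"}
    assert len(results["ethanol"].significant) > 0
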