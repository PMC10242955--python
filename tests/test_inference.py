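"""LR tests, BH-FDR, the pruning workflow, and sex multi-group comparisons."""

import numpy as np
import pytest
import sympy
from hypothesis import given, settings
from hypothesis import strategies as st

import riclpm as rl
from riclpm.inference import comparison_table


def brute_force_bh(p: np.ndarray, alpha: float) -> np.ndarray:
    """Independent step-up enumeration of the Benjamini-Hochberg rule."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    reject = np.zeros(m, dtype=bool)
    k_max = 0
    for k in range(1, m + 1):  # largest k with p_(k) <= k/m * alpha
        if p[order[k - 1]] <= k / m * alpha:
            k_max = k
    reject[order[:k_max]] = True
    return reject


def chi2_sf_oracle(x: float, df: int) -> float:
    """Upper-tail chi-square probability via the regularized upper gamma."""
    val = sympy.uppergamma(sympy.Rational(df, 2), sympy.Float(x) / 2)
    return float(val / sympy.gamma(sympy.Rational(df, 2)))


@pytest.fixture(scope="module")
def fits(single_values):
    ds = rl.simulate_individuals(single_values, 600, seed=83)
    full = rl.fit(rl.build_riclpm(single_values.design), ds, se=False)
    nested = rl.fit(
        rl.build_riclpm(single_values.design, time_constrained=True),
        ds, se=False,
    )
    return full, nested


class TestLRTest:
    def test_identical_models(self, fits):
        full, _ = fits
        dchi, ddf, p = rl.lr_test(full, full)
        assert (dchi, ddf, p) == (0.0, 0, 1.0)

    def test_constrained_vs_unconstrained(self, fits):
        full, nested = fits
        dchi, ddf, p = rl.lr_test(full, nested)
        assert ddf == 7  # (T-2) * (K^2 lags + K(K+1)/2 innovations), K=2, T=3
        assert dchi >= 0
        assert p == pytest.approx(chi2_sf_oracle(dchi, ddf), abs=1e-10)

    def test_printed_chi_square_arithmetic(self):
        """Upper-tail probabilities at the reference statistics reproduce
        the tabulated p-values.  The first pair is internally inconsistent
        at the last printed digit (sf(32.688, 26) = 0.1713, tabulated as
        0.170, evidently computed before rounding the statistic), so it is
        checked to within two units of the final digit."""
        from scipy.stats import chi2

        assert chi2.sf(32.688, 26) == pytest.approx(0.170, abs=2e-3)
        assert chi2.sf(64.238, 26) == pytest.approx(4.403e-5, abs=5e-9)

    def test_tail_probability_matches_gamma_oracle(self):
        from scipy.stats import chi2

        for x, df in [(0.5, 1), (10.55, 6), (32.688, 26), (64.238, 26),
                      (100.0, 3), (1.0, 30)]:
            assert chi2.sf(x, df) == pytest.approx(
                chi2_sf_oracle(x, df), abs=1e-10
            )

    def test_non_nested_pair_rejected(self, single_values):
        ds = rl.simulate_individuals(single_values, 400, seed=89)
        spec = rl.build_riclpm(single_values.design)
        labs = spec.labels(matrix="beta", offdiag=True)
        a = rl.fit(rl.apply_constraints(spec, [{"fix": labs[0]}]), ds, se=False)
        b = rl.fit(rl.apply_constraints(spec, [{"fix": labs[1]}]), ds, se=False)
        with pytest.raises(ValueError, match="not nested"):
            rl.lr_test(a, b)


class TestBHFDR:
    def test_examples(self):
        _, rej = rl.bh_fdr([0.001, 0.01, 0.02, 0.8], alpha=0.05)
        assert rej.sum() == 3
        _, rej = rl.bh_fdr([1.0] * 10, alpha=0.05)
        assert rej.sum() == 0
        _, rej = rl.bh_fdr([0.04], alpha=0.05)
        assert rej.all()
        q, rej = rl.bh_fdr([], alpha=0.05)
        assert len(q) == 0 and len(rej) == 0

    def test_against_brute_force_step_up(self, rng):
        for _ in range(1000):
            m = int(rng.integers(1, 30))
            p = rng.random(m) ** rng.uniform(0.5, 3.0)
            alpha = float(rng.uniform(0.01, 0.2))
            _, rej = rl.bh_fdr(p, alpha)
            np.testing.assert_array_equal(rej, brute_force_bh(p, alpha))

    @settings(max_examples=100, deadline=None)
    @given(
        st.lists(st.floats(0.0, 1.0), min_size=1, max_size=20),
        st.floats(0.01, 0.2),
    )
    def test_qvalues_monotone_in_sorted_order(self, p, alpha):
        q, _ = rl.bh_fdr(p, alpha)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_invalid_pvalues(self):
        with pytest.raises(ValueError):
            rl.bh_fdr([0.5, 1.5])


class TestPruneAndCompare:
    def test_strong_path_retained_null_paths_dropped(self, single_values):
        """With one strong cross-lag in the data the pruned model keeps it;
        absent paths are mostly dropped."""
        import copy

        v = copy.deepcopy(single_values)
        v.beta[:, :, :] = 0.0
        v.beta[0, 0, 0] = v.beta[1, 0, 0] = 0.3
        v.beta[0, 1, 1] = v.beta[1, 1, 1] = 0.3
        v.beta[0, 0, 1] = 0.3  # one strong cross-lag at the first lag
        spec = rl.build_riclpm(v.design)
        ds = rl.simulate_individuals(v, 5000, seed=97)
        res = rl.prune_and_compare(spec, ds, "within_person_cross_lags",
                                   "fdr", 0.05)
        assert "beta_w2_y1_y2" in res.retained
        assert res.fits["pruned"].loglik <= res.fits["full"].loglik + 1e-6
        assert res.fits["null"].loglik <= res.fits["pruned"].loglik + 1e-6
        assert not res.fits["null"].spec.labels(
            matrix="beta", offdiag=True, free=True
        )

    def test_family_size_for_four_traits(self):
        spec = rl.build_riclpm(rl.PanelDesign(4, 3))
        from riclpm.inference import _scope_labels

        assert len(_scope_labels(spec, "within_person_cross_lags")) == 24

    def test_sibling_scope_on_wf_model(self, wf_values):
        spec = rl.build_wf_riclpm(wf_values.design)
        ds = rl.simulate_dataset(wf_values, 800, 800, seed=101)
        res = rl.prune_and_compare(spec, ds, "between_sibling_paths",
                                   "nominal", 0.05)
        assert set(res.table.models["model"]) == {"full", "pruned", "null"}
        assert (res.table.pairs["delta_df"] >= 0).all()
        assert not res.fits["null"].spec.labels(matrix="sib", free=True)

    def test_edge_list_levels(self, single_values):
        spec = rl.build_riclpm(single_values.design)
        ds = rl.simulate_individuals(single_values, 1500, seed=103)
        res = rl.prune_and_compare(spec, ds)
        edges = rl.edge_list(res)
        assert set(edges["level"]) <= {
            "within-person", "between-sibling", "between-person correlation"
        }
        n_lags = len(spec.labels(matrix="beta"))
        assert (edges["level"] == "within-person").sum() == n_lags


@pytest.fixture(scope="module")
def null_sex_data(single_values):
    a = rl.simulate_individuals(single_values, 1200, seed=107)
    b = rl.simulate_individuals(single_values, 1200, seed=109)
    return {"male": a.scores(), "female": b.scores()}


class TestSexMultigroup:
    def test_equated_model_never_fits_better(self, null_sex_data,
                                             single_values):
        spec = rl.build_riclpm(single_values.design)
        table, fits = rl.sex_multigroup_test(spec, null_sex_data)
        assert fits["equated"].loglik <= fits["split"].loglik + 1e-6
        ddf = table.pairs["delta_df"].iloc[0]
        assert ddf == len(spec.labels(matrix="beta"))

    def test_no_spurious_sex_difference(self, null_sex_data, single_values):
        """Identical generating parameters per sex: the split model should
        not be strongly preferred."""
        spec = rl.build_riclpm(single_values.design)
        table, _ = rl.sex_multigroup_test(spec, null_sex_data)
        assert table.pairs["p"].iloc[0] > 0.001

    def test_true_sex_difference_detected(self, single_values):
        import copy

        male = copy.deepcopy(single_values)
        male.beta[:, 0, 1] = 0.35
        dsm = rl.simulate_individuals(male, 2500, seed=113)
        dsf = rl.simulate_individuals(single_values, 2500, seed=127)
        spec = rl.build_riclpm(single_values.design)
        table, _ = rl.sex_multigroup_test(
            spec, {"male": dsm.scores(), "female": dsf.scores()}
        )
        assert table.pairs["p"].iloc[0] < 0.01


def test_comparison_table_round_trip(tmp_path, single_values):
    spec = rl.build_riclpm(single_values.design)
    ds = rl.simulate_individuals(single_values, 400, seed=131)
    res = rl.fit(spec, ds, se=False)
    table = comparison_table([("full", res)])
    path = tmp_path / "cmp.tsv"
    table.to_tsv(path)
    assert "chi_square" in path.read_text()
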