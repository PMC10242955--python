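"""Parameter-table bookkeeping, implied moments, and constraint edits."""

import copy

import numpy as np
import pytest

import riclpm as rl
from riclpm.model_builder import (
    ConstraintConflictError,
    DesignError,
    IdentificationError,
    ValidationError,
    _group_mats,
)

from conftest import random_parameter_set


def _free_count_oracle(K: int, T: int, constrained: bool) -> int:
    """Independent closed-form count of free parameters in a RI-CLPM."""
    tri = K * (K + 1) // 2
    free = T * K + 2 * tri + (T - 1) * K * K + (T - 1) * tri
    if constrained:
        free -= (T - 2) * (K * K + tri)
    return free


def _moment_count_oracle(d: int, n_groups: int = 1) -> int:
    return n_groups * (d + d * (d + 1) // 2)


class TestDegreesOfFreedom:
    @pytest.mark.parametrize("K", [1, 2, 3, 4])
    @pytest.mark.parametrize("T", [3, 4])
    @pytest.mark.parametrize("constrained", [False, True])
    def test_riclpm_counts_match_enumeration(self, K, T, constrained):
        spec = rl.build_riclpm(rl.PanelDesign(K, T), time_constrained=constrained)
        assert spec.n_free == _free_count_oracle(K, T, constrained)
        assert spec.n_moments == _moment_count_oracle(K * T)
        assert spec.df == spec.n_moments - spec.n_free

    def test_four_trait_three_wave_df(self):
        """The 4-trait, 3-wave unconstrained model has 84 free parameters,
        90 observed moments, and 6 model df."""
        spec = rl.build_riclpm(rl.PanelDesign(4, 3))
        assert (spec.n_free, spec.n_moments, spec.df) == (84, 90, 6)

    def test_time_constraint_releases_26_df(self):
        """Equating lags and innovations across the two lags of a 4-trait,
        3-wave model frees 26 fewer parameters."""
        design = rl.PanelDesign(4, 3)
        free = rl.build_riclpm(design)
        constrained = rl.build_riclpm(design, time_constrained=True)
        assert constrained.df - free.df == 26

    def test_two_trait_df(self):
        spec = rl.build_riclpm(rl.PanelDesign(2, 3))
        assert (spec.n_free, spec.n_moments, spec.df) == (26, 27, 1)

    @pytest.mark.parametrize("K,T", [(1, 3), (2, 3), (2, 4), (4, 3)])
    def test_wf_counts_match_enumeration(self, K, T):
        spec = rl.build_wf_riclpm(rl.PanelDesign.twin(K, T))
        tri = K * (K + 1) // 2
        free = (
            _free_count_oracle(K, T, False)
            + (T - 1) * K * K          # between-sibling lags
            + 2 * 2 * tri              # psi_cross, phi1_cross per zygosity
            + 2 * (T - 1) * tri        # theta_cross per zygosity and wave
        )
        assert spec.n_free == free
        assert spec.n_moments == _moment_count_oracle(2 * K * T, n_groups=2)

    def test_wf_four_trait_df(self):
        spec = rl.build_wf_riclpm(rl.PanelDesign.twin(4, 3))
        assert (spec.n_free, spec.n_moments, spec.df) == (196, 648, 452)

    def test_wf_within_person_parameters_appear_once(self):
        """Within-person parameters are shared across siblings and zygosity:
        the wf table holds exactly one copy of each."""
        single = rl.build_riclpm(rl.PanelDesign(1, 3))
        wf = rl.build_wf_riclpm(rl.PanelDesign.twin(1, 3))
        within = ("mu", "psi", "phi1", "beta", "theta")
        for m in within:
            assert len(wf.labels(matrix=m)) == len(single.labels(matrix=m))

    def test_design_errors(self):
        with pytest.raises(IdentificationError):
            rl.PanelDesign(2, 2)
        with pytest.raises(DesignError):
            rl.PanelDesign(0, 3)
        with pytest.raises(DesignError):
            rl.build_riclpm(rl.PanelDesign.twin(2, 3))
        with pytest.raises(DesignError):
            rl.build_wf_riclpm(rl.PanelDesign(2, 3))
        with pytest.raises(DesignError):
            rl.build_wf_riclpm(
                rl.PanelDesign(2, 3, n_siblings=2, groups=("A", "B"))
            )


class TestImpliedMoments:
    def test_zero_lag_compound_symmetry(self):
        """With all lags zero the covariance is psi everywhere off the
        diagonal blocks and psi + residual variance on them."""
        design = rl.PanelDesign(1, 3)
        ps = rl.ParameterSet(
            design,
            np.zeros((3, 1)),
            [[0.7]],
            [[0.4]],
            beta=np.zeros((2, 1, 1)),
            theta=[[[0.3]], [[0.2]]],
        )
        _, S = rl.population_moments(ps)["all"]
        assert S[0, 1] == pytest.approx(0.7, abs=1e-12)
        assert S[0, 2] == pytest.approx(0.7, abs=1e-12)
        assert S[1, 2] == pytest.approx(0.7, abs=1e-12)
        assert np.allclose(np.diag(S), [1.1, 1.0, 0.9], atol=1e-12)

    def test_single_lag_propagation(self):
        """psi=1, phi1=1, lag 0.5 at wave 2 gives cov(x1,x2)=1.5 and
        var(x2)=2.25 (frozen against a Monte-Carlo oracle)."""
        design = rl.PanelDesign(1, 3)
        ps = rl.ParameterSet(
            design,
            np.zeros((3, 1)),
            [[1.0]],
            [[1.0]],
            beta=[[[0.5]], [[0.0]]],
            theta=[[[1.0]], [[1.0]]],
        )
        _, S = rl.population_moments(ps)["all"]
        assert S[0, 1] == pytest.approx(1.5, abs=1e-12)
        assert S[1, 1] == pytest.approx(2.25, abs=1e-12)

    def test_matches_monte_carlo(self, wf_values):
        """Closed-form moments agree with simulation within 3 MC standard
        errors elementwise."""
        n = 200_000
        ds = rl.simulate_dataset(wf_values, n, 0, seed=101)
        X = ds.group_arrays()["MZ"]
        S_emp = np.cov(X.T)
        m_emp = X.mean(axis=0)
        m_pop, S_pop = rl.population_moments(wf_values)["MZ"]
        d = len(m_pop)
        var = np.diag(S_pop)
        se_cov = np.sqrt(
            (np.outer(var, var) + S_pop**2) / n
        )  # large-sample SE of a Gaussian covariance
        assert np.all(np.abs(S_emp - S_pop) < 3.5 * se_cov)
        assert np.all(np.abs(m_emp - m_pop) < 3.5 * np.sqrt(var / n))

    def test_twin_exchange_symmetry(self, rng):
        """Permuting the two siblings' blocks leaves the implied covariance
        unchanged for arbitrary parameter sets."""
        for _ in range(20):
            vals = random_parameter_set(2, 3, pair=True, rng=rng)
            _, S = rl.population_moments(vals)["DZ"]
            d = S.shape[0] // 2
            perm = np.concatenate([np.arange(d, 2 * d), np.arange(d)])
            assert np.allclose(S[np.ix_(perm, perm)], S, atol=1e-12)

    def test_reduction_to_single_person(self, wf_values):
        """Zero sibling paths and zero cross-twin blocks reproduce the
        single-person RI-CLPM covariance exactly."""
        v = copy.deepcopy(wf_values)
        v.beta_sib[:] = 0.0
        for z in ("MZ", "DZ"):
            v.psi_cross[z][:] = 0.0
            v.phi1_cross[z][:] = 0.0
            v.theta_cross[z][:] = 0.0
        m_s, S_s = rl.population_moments(v.marginal_single())["all"]
        d = len(m_s)
        for z in ("MZ", "DZ"):
            m_w, S_w = rl.population_moments(v)[z]
            assert np.max(np.abs(S_w[:d, :d] - S_s)) < 1e-12
            assert np.max(np.abs(S_w[d:, d:] - S_s)) < 1e-12
            assert np.max(np.abs(S_w[:d, d:])) < 1e-12
            assert np.max(np.abs(m_w[:d] - m_s)) < 1e-12

    def test_rejects_non_psd_input(self):
        design = rl.PanelDesign(2, 3)
        bad = rl.ParameterSet(
            design,
            np.zeros((3, 2)),
            [[1.0, 2.0], [2.0, 1.0]],  # not PSD
            np.eye(2),
            beta=np.zeros((2, 2, 2)),
            theta=np.stack([np.eye(2)] * 2),
        )
        spec = rl.build_riclpm(design)
        with pytest.raises(ValidationError):
            rl.implied_moments(spec, bad)

    def test_spec_implied_matches_parameter_moments(self, rng):
        """The spec's internal moment map and the standalone parameter-set
        map agree at matching values."""
        vals = random_parameter_set(2, 3, pair=True, rng=rng)
        spec = rl.build_wf_riclpm(vals.design)
        # place the true values into the free vector via the mats layout
        theta = np.empty(spec.n_free)
        eq_index = {eq: i for i, eq in enumerate(spec.free_eq_ids)}
        for p in spec.params:
            if p.free:
                g = p.group or spec.groups[0]
                theta[eq_index[p.eq]] = _group_mats(vals, g)[p.matrix][p.loc]
        by_spec = spec.implied(theta)
        direct = rl.population_moments(vals)
        for z in spec.groups:
            assert np.allclose(by_spec[z][1], direct[z][1], atol=1e-12)
            assert np.allclose(by_spec[z][0], direct[z][0], atol=1e-12)


class TestApplyConstraints:
    def test_empty_edit_is_identity(self):
        spec = rl.build_riclpm(rl.PanelDesign(2, 3))
        out = rl.apply_constraints(spec, [])
        assert out.parameter_table().equals(spec.parameter_table())
        assert out is not spec

    def test_fixing_cross_lags_gives_null_model(self):
        spec = rl.build_riclpm(rl.PanelDesign(4, 3))
        cross = spec.labels(matrix="beta", offdiag=True)
        assert len(cross) == 24  # 12 cross-lags per lag x 2 lags
        null = rl.apply_constraints(
            spec, [{"fix": lab, "value": 0.0} for lab in cross]
        )
        assert spec.n_free - null.n_free == 24
        assert not null.labels(matrix="beta", offdiag=True, free=True)

    def test_refix_conflict(self):
        spec = rl.build_riclpm(rl.PanelDesign(2, 3))
        lab = spec.labels(matrix="beta")[0]
        once = rl.apply_constraints(spec, [{"fix": lab, "value": 0.0}])
        rl.apply_constraints(once, [{"fix": lab, "value": 0.0}])  # same: fine
        with pytest.raises(ConstraintConflictError):
            rl.apply_constraints(once, [{"fix": lab, "value": 0.5}])

    def test_merge_reduces_free_count(self):
        spec = rl.build_riclpm(rl.PanelDesign(2, 3))
        labs = spec.labels(matrix="beta")[:2]
        merged = rl.apply_constraints(spec, [{"merge": labs}])
        assert merged.n_free == spec.n_free - 1

    def test_split_by_group(self):
        design = rl.PanelDesign(2, 3, groups=("male", "female"))
        spec = rl.ModelSpec(design, "riclpm", rl.build_riclpm(
            rl.PanelDesign(2, 3)).copy().params)
        lab = spec.labels(matrix="beta")[0]
        split = rl.apply_constraints(spec, [{"split_by_group": lab}])
        assert split.n_free == spec.n_free + 1
        assert f"{lab}_male" in split.labels(matrix="beta")
        assert f"{lab}_female" in split.labels(matrix="beta")

    def test_fixing_merged_group_fixes_all_members(self):
        spec = rl.build_riclpm(rl.PanelDesign(2, 3), time_constrained=True)
        lab = spec.labels(matrix="beta")[0]
        eq = spec.param(lab).eq
        members = [p.label for p in spec.params if p.free and p.eq == eq]
        assert len(members) == 2  # one per lag
        fixed = rl.apply_constraints(spec, [{"fix": lab, "value": 0.0}])
        for m in members:
            assert not fixed.param(m).free


class TestSerialization:
    def test_tsv_round_trip(self, tmp_path):
        spec = rl.build_wf_riclpm(rl.PanelDesign.twin(2, 3))
        path = tmp_path / "spec.tsv"
        spec.to_tsv(path)
        back = rl.ModelSpec.from_tsv(path, spec.design, spec.kind)
        assert back.df == spec.df
        assert back.free_eq_ids == spec.free_eq_ids
        theta = spec.start_vector()
        for g in spec.groups:
            np.testing.assert_allclose(
                back.implied(theta)[g][1], spec.implied(theta)[g][1]
            )
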