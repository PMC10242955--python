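"""Generative simulation of twin-pair longitudinal panels.

The generator draws data under the wf-RI-CLPM process: family-level random
intercepts and wave-1 deviations from a zygosity-specific joint Gaussian,
then a first-order vector autoregression of the stacked twin-pair deviation
vector with Gaussian innovations.  Cross-twin covariance blocks can be
derived from classical biometric (ACE/ADE) variance shares, so the MZ/DZ
correlation structure of the simulated panel reflects additive-genetic,
shared-environment (or dominance) and unique-environment contributions.

All random components are Gaussian and missingness is completely at random;
see the methods note for what this emulates and what it leaves out.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model_builder import (
    PanelDesign,
    ParameterSet,
    ValidationError,
    parameter_moments,
)

__all__ = [
    "BiometricComponent",
    "BiometricSpec",
    "biometric_to_phenotypic",
    "simulate_dataset",
    "simulate_individuals",
    "population_moments",
    "default_parameters",
]


@dataclass(frozen=True)
class BiometricComponent:
    """ACE or ADE variance shares for one variance component.

    ``a2`` is the additive-genetic share; ``c2_or_d2`` is the shared
    environment share under ACE or the dominance share under ADE; ``e2`` is
    the unique-environment share.  Shares must sum to 1.
    """

    model: str  # 'ACE' | 'ADE'
    a2: float
    c2_or_d2: float
    e2: float

    def __post_init__(self) -> None:
        if self.model not in ("ACE", "ADE"):
            raise ValidationError("biometric model must be 'ACE' or 'ADE'")
        for name, v in (("a2", self.a2), ("c2_or_d2", self.c2_or_d2), ("e2", self.e2)):
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0, 1]")
        if abs(self.a2 + self.c2_or_d2 + self.e2 - 1.0) > 1e-10:
            raise ValidationError("biometric shares must sum to 1")

    @property
    def r_mz(self) -> float:
        """Implied MZ cross-twin correlation: a2 + c2 (ACE) or a2 + d2 (ADE)."""
        return self.a2 + self.c2_or_d2

    @property
    def r_dz(self) -> float:
        """Implied DZ cross-twin correlation: a2/2 + c2 (ACE) or a2/2 + d2/4 (ADE)."""
        if self.model == "ACE":
            return 0.5 * self.a2 + self.c2_or_d2
        return 0.5 * self.a2 + 0.25 * self.c2_or_d2

    def r(self, zygosity: str) -> float:
        return self.r_mz if zygosity == "MZ" else self.r_dz


@dataclass
class BiometricSpec:
    """Biometric structure for every variance component of a twin design.

    ``intercept[k]`` gives the shares for trait ``k``'s random intercept;
    ``residual[t][k]`` gives the shares for the wave-``t`` age-specific
    residual of trait ``k`` (wave 1 = exogenous deviation, waves 2..T =
    innovations).
    """

    intercept: list[BiometricComponent]
    residual: list[list[BiometricComponent]]  # T x K


def biometric_to_phenotypic(
    biometric: BiometricSpec,
    total_variances: dict[str, np.ndarray],
    mu: np.ndarray,
    beta: np.ndarray,
    beta_sib: np.ndarray,
    design: PanelDesign | None = None,
) -> ParameterSet:
    """Build a wf-RI-CLPM parameter set from biometric shares.

    ``total_variances`` maps ``"intercept"`` to the per-trait intercept
    variances (K,) and ``"residual"`` to the per-wave/trait residual
    variances (T, K).  Within-person covariance blocks are diagonal;
    cross-twin diagonals are the within variances scaled by the implied
    MZ/DZ correlation of each component's biometric model, so e.g. the
    ratio ``psi_cross[z][k,k] / psi[k,k]`` equals that component's cross-twin
    correlation.
    """
    v_int = np.asarray(total_variances["intercept"], float)
    v_res = np.asarray(total_variances["residual"], float)
    mu = np.asarray(mu, float)
    beta = np.asarray(beta, float)
    beta_sib = np.asarray(beta_sib, float)
    T, K = v_res.shape
    if design is None:
        design = PanelDesign.twin(K, T)
    if len(biometric.intercept) != K or len(biometric.residual) != T:
        raise ValidationError("biometric spec does not match the design")

    psi = np.diag(v_int)
    phi1 = np.diag(v_res[0])
    theta = np.stack([np.diag(v_res[t]) for t in range(1, T)])
    psi_cross, phi1_cross, theta_cross = {}, {}, {}
    for z in ("MZ", "DZ"):
        psi_cross[z] = np.diag(
            [biometric.intercept[k].r(z) * v_int[k] for k in range(K)]
        )
        phi1_cross[z] = np.diag(
            [biometric.residual[0][k].r(z) * v_res[0, k] for k in range(K)]
        )
        theta_cross[z] = np.stack(
            [
                np.diag(
                    [biometric.residual[t][k].r(z) * v_res[t, k] for k in range(K)]
                )
                for t in range(1, T)
            ]
        )
    values = ParameterSet(
        design,
        mu,
        psi,
        phi1,
        beta,
        theta,
        beta_sib=beta_sib,
        psi_cross=psi_cross,
        phi1_cross=phi1_cross,
        theta_cross=theta_cross,
    )
    values.validate()
    return values


def default_parameters(
    n_traits: int = 4,
    n_waves: int = 3,
    intercept_share: float = 0.5,
    carry_over: float = 0.2,
    cross_lag: float = 0.1,
    sibling_path: float = 0.05,
    intercept_corr: float = 0.45,
    a2: float = 0.6,
    c2: float = 0.1,
) -> ParameterSet:
    """Study-like wf-RI-CLPM parameters for standardized scores.

    Defaults emulate the cohort structure the model targets: unit-variance
    traits with random intercepts carrying about half of the variance,
    positively correlated intercepts, carry-over effects of 0.2, cross-lags
    of 0.1, small positive sibling paths, and an additive-genetic ACE
    structure (a2=0.6, c2=0.1) for every component.
    """
    design = PanelDesign.twin(n_traits, n_waves)
    K, T = n_traits, n_waves
    comp = BiometricComponent("ACE", a2, c2, 1.0 - a2 - c2)
    bio = BiometricSpec(
        intercept=[comp] * K, residual=[[comp] * K for _ in range(T)]
    )
    resid_share = 1.0 - intercept_share
    B = np.full((K, K), cross_lag) + np.eye(K) * (carry_over - cross_lag)
    beta = np.stack([B] * (T - 1))
    beta_sib = np.full((T - 1, K, K), sibling_path)
    # innovation variances chosen so deviation variances stay near resid_share
    innov = np.empty((T, K))
    innov[0] = resid_share
    prev = np.full(K, resid_share)
    for t in range(1, T):
        structural = np.diag(B @ np.diag(prev) @ B.T)
        innov[t] = np.clip(resid_share - structural, 0.05, None)
        prev = structural + innov[t]
    values = biometric_to_phenotypic(
        bio,
        {"intercept": np.full(K, intercept_share), "residual": innov},
        mu=np.zeros((T, K)),
        beta=beta,
        beta_sib=beta_sib,
        design=design,
    )
    # positively correlated intercepts, mirrored in the cross-twin blocks
    off = intercept_corr * intercept_share
    values.psi += off * (np.ones((K, K)) - np.eye(K))
    for z in ("MZ", "DZ"):
        values.psi_cross[z] += comp.r(z) * off * (np.ones((K, K)) - np.eye(K))
    values.validate()
    return values


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------


def _safe_chol(cov: np.ndarray, name: str) -> np.ndarray:
    """Cholesky-like factor tolerating PSD-singular blocks."""
    sym = 0.5 * (cov + cov.T)
    vals = np.linalg.eigvalsh(sym)
    scale = max(1.0, float(np.max(np.abs(sym))))
    if vals.min() < -1e-8 * scale:
        raise ValidationError(f"{name} is not positive semi-definite")
    try:
        return np.linalg.cholesky(sym)
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh(sym)
        return V * np.sqrt(np.clip(w, 0.0, None))


def _simulate_block(
    values: ParameterSet, zygosity: str | None, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Simulate ``n`` families (or persons) as an (n, d) score matrix."""
    design = values.design
    T, K = design.n_waves, design.n_traits
    pair = values.is_pair
    m = 2 * K if pair else K
    if pair:
        psi = np.block(
            [[values.psi, values.psi_cross[zygosity]],
             [values.psi_cross[zygosity].T, values.psi]]
        )
        phi1 = np.block(
            [[values.phi1, values.phi1_cross[zygosity]],
             [values.phi1_cross[zygosity].T, values.phi1]]
        )
        lags = [
            np.block(
                [[values.beta[w], values.beta_sib[w]],
                 [values.beta_sib[w], values.beta[w]]]
            )
            for w in range(T - 1)
        ]
        innov = [
            np.block(
                [[values.theta[w], values.theta_cross[zygosity][w]],
                 [values.theta_cross[zygosity][w].T, values.theta[w]]]
            )
            for w in range(T - 1)
        ]
        tag = f" ({zygosity})" if zygosity else ""
    else:
        psi, phi1 = values.psi, values.phi1
        lags = [values.beta[w] for w in range(T - 1)]
        innov = [values.theta[w] for w in range(T - 1)]
        tag = ""

    intercepts = rng.standard_normal((n, m)) @ _safe_chol(
        psi, f"joint intercept covariance{tag}"
    ).T
    dev = rng.standard_normal((n, m)) @ _safe_chol(
        phi1, f"joint wave-1 deviation covariance{tag}"
    ).T
    waves = [dev]
    for t in range(1, T):
        e = rng.standard_normal((n, m)) @ _safe_chol(
            innov[t - 1], f"joint innovation covariance at wave {t + 1}{tag}"
        ).T
        dev = waves[-1] @ lags[t - 1].T + e
        waves.append(dev)

    # scores in sibling-major order: sib 1 all waves/traits, then sib 2
    n_sib = 2 if pair else 1
    out = np.empty((n, n_sib * T * K))
    for s in range(n_sib):
        for t in range(T):
            block = waves[t][:, s * K : (s + 1) * K] + intercepts[:, s * K : (s + 1) * K]
            out[:, s * T * K + t * K : s * T * K + (t + 1) * K] = block + values.mu[t]
    return out


def simulate_dataset(
    values: ParameterSet,
    n_mz: int,
    n_dz: int,
    seed: int | np.random.Generator,
    missing_rate: float = 0.0,
):
    """Simulate a twin-pair panel under the wf-RI-CLPM generative process.

    Returns a :class:`riclpm.data_io.TwinDataset` with ``n_mz`` MZ and
    ``n_dz`` DZ families.  ``missing_rate`` applies MCAR missingness to each
    individual score cell.  Identical seeds give bit-identical datasets.
    """
    from .data_io import TwinDataset, score_columns

    if not values.is_pair:
        raise ValidationError(
            "simulate_dataset requires a twin-pair parameter set; use "
            "simulate_individuals for single-person panels"
        )
    values.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    blocks, zyg = [], []
    for z, n in (("MZ", n_mz), ("DZ", n_dz)):
        if n > 0:
            blocks.append(_simulate_block(values, z, n, rng))
            zyg.extend([z] * n)
    cols = score_columns(values.design)
    scores = np.vstack(blocks) if blocks else np.empty((0, len(cols)))
    if missing_rate > 0 and scores.size:
        mask = rng.random(scores.shape) < missing_rate
        scores = scores.copy()
        scores[mask] = np.nan
    df = pd.DataFrame(scores, columns=cols)
    df.insert(0, "zygosity", zyg)
    df.insert(0, "family_id", [f"fam{i:06d}" for i in range(len(df))])
    return TwinDataset(df, values.design)


def simulate_individuals(
    values: ParameterSet,
    n: int,
    seed: int | np.random.Generator,
    missing_rate: float = 0.0,
):
    """Simulate a single-person panel under the RI-CLPM process."""
    from .data_io import TwinDataset, score_columns

    if values.is_pair:
        raise ValidationError("simulate_individuals requires a single-person set")
    values.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    scores = (
        _simulate_block(values, None, n, rng)
        if n > 0
        else np.empty((0, values.design.d))
    )
    if missing_rate > 0 and scores.size:
        mask = rng.random(scores.shape) < missing_rate
        scores[mask] = np.nan
    df = pd.DataFrame(scores, columns=score_columns(values.design))
    df.insert(0, "family_id", [f"ind{i:06d}" for i in range(len(df))])
    return TwinDataset(df, values.design)


def population_moments(
    values: ParameterSet,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Exact per-group population mean and covariance of the process.

    Delegates to the closed-form moment map used by the model builder, so
    simulation output can be checked against it as an oracle.
    """
    return parameter_moments(values)
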