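"""Falconer variance decomposition of wf-RI-CLPM twin correlations.

Fitting the within-family model to MZ and DZ pairs yields cross-twin
covariance blocks for the random intercepts and for every age-specific
residual component.  Scaling each block by the corresponding within-person
variance gives latent MZ and DZ twin correlations, from which classical
Falconer comparisons estimate variance shares: the additive-genetic share
a2 is twice the difference between the MZ and DZ correlations under ACE.
When the DZ correlation falls below half the MZ correlation an ADE
parameterization is used instead (dominance in place of the shared
environment).  Estimates are reported unclipped: negative components and
overdominance (d2 > 1, typically driven by near-zero DZ correlations) are
flagged rather than truncated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimator import FitResult

__all__ = [
    "VarianceDecomposition",
    "twin_correlations",
    "falconer_decompose",
    "decompose_fit",
    "write_decomposition",
]


@dataclass
class VarianceDecomposition:
    """ACE/ADE shares for one variance component, with range flags."""

    component: str
    r_mz: float
    r_dz: float
    model: str  # 'ACE' | 'ADE'
    a2: float
    c2_or_d2: float
    e2: float
    flags: set[str] = field(default_factory=set)

    @property
    def overdominance(self) -> bool:
        return "overdominance" in self.flags

    @property
    def negative_component(self) -> bool:
        return "negative_component" in self.flags


def falconer_decompose(
    r_mz: float, r_dz: float, component: str = ""
) -> VarianceDecomposition:
    """Falconer variance shares from MZ/DZ correlations.

    ACE when ``r_dz >= r_mz / 2``: a2 = 2(r_mz - r_dz), c2 = 2 r_dz - r_mz;
    otherwise ADE: a2 = 4 r_dz - r_mz, d2 = 2 r_mz - 4 r_dz.  In both cases
    e2 = 1 - r_mz.  The two branches agree (c2 = d2 = 0) at the boundary.
    """
    if not (-1.0 <= r_mz <= 1.0 and -1.0 <= r_dz <= 1.0):
        raise ValueError("twin correlations must lie in [-1, 1]")
    if r_dz >= r_mz / 2.0:
        model = "ACE"
        a2 = 2.0 * (r_mz - r_dz)
        x2 = 2.0 * r_dz - r_mz
    else:
        model = "ADE"
        a2 = 4.0 * r_dz - r_mz
        x2 = 2.0 * r_mz - 4.0 * r_dz
    e2 = 1.0 - r_mz
    flags = set()
    if x2 > 1.0:
        flags.add("overdominance")
    if a2 < 0 or x2 < 0 or e2 < 0:
        flags.add("negative_component")
    return VarianceDecomposition(component, r_mz, r_dz, model, a2, x2, e2, flags)


def twin_correlations(fit_result: FitResult) -> pd.DataFrame:
    """Latent MZ/DZ correlations per random intercept and residual component.

    Each correlation is the estimated cross-twin covariance divided by the
    within-person variance of the same component.  Components with a
    non-positive within-person variance are skipped with a warning.
    """
    spec = fit_result.spec
    if spec.kind != "wf":
        raise ValueError("twin correlations require a wf-RI-CLPM fit")
    ps = fit_result.parameter_set()
    design = spec.design
    tl, wl = design.trait_labels, design.wave_labels
    rows = []

    def _add(name, within, cross_by_z):
        if within <= 0:
            warnings.warn(
                f"component {name} has non-positive within-person variance; "
                "skipped"
            )
            return
        rows.append(
            {
                "component": name,
                "r_mz": cross_by_z["MZ"] / within,
                "r_dz": cross_by_z["DZ"] / within,
            }
        )

    K, T = design.n_traits, design.n_waves
    for k in range(K):
        _add(
            f"intercept:{tl[k]}",
            ps.psi[k, k],
            {z: ps.psi_cross[z][k, k] for z in ("MZ", "DZ")},
        )
    for k in range(K):
        _add(
            f"residual:{tl[k]}@{wl[0]}",
            ps.phi1[k, k],
            {z: ps.phi1_cross[z][k, k] for z in ("MZ", "DZ")},
        )
        for w in range(T - 1):
            _add(
                f"residual:{tl[k]}@{wl[w + 1]}",
                ps.theta[w][k, k],
                {z: ps.theta_cross[z][w][k, k] for z in ("MZ", "DZ")},
            )
    return pd.DataFrame(rows)


def decompose_fit(fit_result: FitResult) -> pd.DataFrame:
    """Falconer decomposition of every component of a wf-RI-CLPM fit."""
    corrs = twin_correlations(fit_result)
    rows = []
    for _, r in corrs.iterrows():
        dec = falconer_decompose(r["r_mz"], r["r_dz"], r["component"])
        rows.append(
            {
                "component": dec.component,
                "r_mz": dec.r_mz,
                "r_dz": dec.r_dz,
                "model": dec.model,
                "a2": dec.a2,
                "c2_or_d2": dec.c2_or_d2,
                "e2": dec.e2,
                "flags": ",".join(sorted(dec.flags)),
            }
        )
    return pd.DataFrame(rows)


def write_decomposition(fit_result: FitResult, path) -> None:
    decompose_fit(fit_result).to_csv(path, sep="\t", index=False)
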