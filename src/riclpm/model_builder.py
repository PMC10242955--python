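"""Model specifications for random-intercept cross-lagged panel models.

A RI-CLPM for ``K`` traits measured at ``T`` waves decomposes each observed
score into a wave/trait group mean, a time-invariant person-specific random
intercept, and a within-person deviation that follows a first-order vector
autoregression across waves.  The random intercepts absorb stable
between-person differences (for example genetic and family-environmental
confounds with constant effects), so the lagged regressions among deviations
estimate genuinely within-person carry-over and cross-trait effects.

The within-family extension (wf-RI-CLPM) models both members of a twin pair
jointly.  Deviations of one twin may lag onto the co-twin's deviations
(between-sibling paths, shared across zygosity and direction), while random
intercepts, wave-1 deviations and wave-specific innovations acquire
cross-twin covariance blocks that are estimated separately for monozygotic
and dizygotic pairs.  Comparing those blocks across zygosity supports a
Falconer-style variance decomposition downstream (see
:mod:`riclpm.biometrics`).

Identification conventions: random-intercept factor loadings are fixed to 1
at every wave, intercepts are uncorrelated with wave-1 deviations, wave-1
deviations are exogenous with free (co)variances, and means are shared
across siblings and zygosity groups.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, replace
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DesignError",
    "IdentificationError",
    "ConstraintConflictError",
    "ValidationError",
    "PanelDesign",
    "ParameterSet",
    "Param",
    "ModelSpec",
    "build_riclpm",
    "build_wf_riclpm",
    "implied_moments",
    "parameter_moments",
    "apply_constraints",
]

_PSD_TOL = 1e-8

#: matrices that are symmetric in their trailing two dimensions
SYMMETRIC_MATRICES = frozenset(
    {"psi", "phi1", "theta", "psi_c", "phi1_c", "theta_c"}
)


class DesignError(ValueError):
    """Invalid panel design (trait/wave/sibling layout)."""


class IdentificationError(ValueError):
    """More free parameters than distinct observed moments, or too few waves."""


class ConstraintConflictError(ValueError):
    """Conflicting constraint edits on a model specification."""


class ValidationError(ValueError):
    """Parameter values violate structural requirements (shape, symmetry, PSD)."""


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PanelDesign:
    """Layout of a longitudinal (twin) panel: traits x waves x siblings.

    Parameters
    ----------
    n_traits
        Number of traits ``K`` (>= 1).
    n_waves
        Number of measurement occasions ``T``.  At least three waves are
        required: with two waves the lagged structure is saturated and the
        constrained/unconstrained contrast is empty.
    trait_labels, wave_labels
        Identifiers used in column names and parameter labels.  Defaults are
        ``y1..yK`` and ``1..T``.
    n_siblings
        1 for single-person panels, 2 for twin-pair panels.
    groups
        Estimation groups.  ``("all",)`` for a plain RI-CLPM,
        ``("MZ", "DZ")`` for the within-family model, or e.g.
        ``("male", "female")`` for sex multi-group variants.
    """

    n_traits: int
    n_waves: int
    trait_labels: tuple[str, ...] = ()
    wave_labels: tuple[str, ...] = ()
    n_siblings: int = 1
    groups: tuple[str, ...] = ("all",)

    def __post_init__(self) -> None:
        if self.n_traits < 1:
            raise DesignError("n_traits must be >= 1")
        if self.n_waves < 3:
            raise IdentificationError(
                "at least 3 waves are required for a (wf-)RI-CLPM"
            )
        if self.n_siblings not in (1, 2):
            raise DesignError("n_siblings must be 1 or 2")
        if not self.trait_labels:
            object.__setattr__(
                self,
                "trait_labels",
                tuple(f"y{k + 1}" for k in range(self.n_traits)),
            )
        if not self.wave_labels:
            object.__setattr__(
                self, "wave_labels", tuple(str(t + 1) for t in range(self.n_waves))
            )
        object.__setattr__(self, "trait_labels", tuple(self.trait_labels))
        object.__setattr__(self, "wave_labels", tuple(self.wave_labels))
        object.__setattr__(self, "groups", tuple(self.groups))
        if len(self.trait_labels) != self.n_traits:
            raise DesignError("trait_labels length must equal n_traits")
        if len(self.wave_labels) != self.n_waves:
            raise DesignError("wave_labels length must equal n_waves")
        if len(set(self.groups)) != len(self.groups) or not self.groups:
            raise DesignError("groups must be a non-empty list of unique labels")

    @property
    def d(self) -> int:
        """Length of the observed vector per family (siblings x waves x traits)."""
        return self.n_siblings * self.n_waves * self.n_traits

    @classmethod
    def twin(
        cls,
        n_traits: int,
        n_waves: int,
        trait_labels: Sequence[str] = (),
        wave_labels: Sequence[str] = (),
    ) -> "PanelDesign":
        """Two-sibling design with MZ/DZ groups, as used by the wf-RI-CLPM."""
        return cls(
            n_traits,
            n_waves,
            tuple(trait_labels),
            tuple(wave_labels),
            n_siblings=2,
            groups=("MZ", "DZ"),
        )

    def with_groups(self, groups: Sequence[str]) -> "PanelDesign":
        return replace(self, groups=tuple(groups))


# ---------------------------------------------------------------------------
# parameter values
# ---------------------------------------------------------------------------


@dataclass
class ParameterSet:
    """Numeric parameter values of a (wf-)RI-CLPM generative process.

    Arrays follow the convention that lag/innovation matrices are indexed by
    target wave ``t = 2..T`` (array index ``t - 2``) and regression matrices
    have the outcome trait on rows and the predictor trait on columns.

    Attributes
    ----------
    mu : (T, K)
        Wave/trait means, shared across siblings and groups.
    psi : (K, K)
        Random-intercept covariance within a person.
    phi1 : (K, K)
        Covariance of the exogenous wave-1 deviations within a person.
    beta : (T-1, K, K)
        Within-person lag matrices; diagonal entries are carry-over
        (autoregressive) effects, off-diagonals are cross-lags.
    theta : (T-1, K, K)
        Innovation covariances within a person at waves ``2..T``.
    beta_sib : (T-1, K, K), optional
        Between-sibling lag matrices, shared across zygosity and across the
        twin1->twin2 / twin2->twin1 direction.
    psi_cross, phi1_cross : {zygosity: (K, K)}, optional
        Cross-twin covariance blocks per zygosity; symmetric under twin
        exchange (each block equals its own transpose).
    theta_cross : {zygosity: (T-1, K, K)}, optional
        Cross-twin innovation covariance blocks per zygosity and wave.
    """

    design: PanelDesign
    mu: np.ndarray
    psi: np.ndarray
    phi1: np.ndarray
    beta: np.ndarray
    theta: np.ndarray
    beta_sib: np.ndarray | None = None
    psi_cross: dict[str, np.ndarray] | None = None
    phi1_cross: dict[str, np.ndarray] | None = None
    theta_cross: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, float)
        self.psi = np.asarray(self.psi, float)
        self.phi1 = np.asarray(self.phi1, float)
        self.beta = np.asarray(self.beta, float)
        self.theta = np.asarray(self.theta, float)
        if self.beta_sib is not None:
            self.beta_sib = np.asarray(self.beta_sib, float)
        for attr in ("psi_cross", "phi1_cross", "theta_cross"):
            val = getattr(self, attr)
            if val is not None:
                setattr(self, attr, {z: np.asarray(m, float) for z, m in val.items()})

    @property
    def is_pair(self) -> bool:
        return self.beta_sib is not None

    def validate(self) -> None:
        """Check shapes, symmetry and positive semi-definiteness.

        Raises :class:`ValidationError` naming the offending block, including
        the zygosity-specific stacked twin-pair blocks for pair models.
        """
        T, K = self.design.n_waves, self.design.n_traits
        _expect_shape(self.mu, (T, K), "mu")
        _expect_shape(self.psi, (K, K), "psi")
        _expect_shape(self.phi1, (K, K), "phi1")
        _expect_shape(self.beta, (T - 1, K, K), "beta")
        _expect_shape(self.theta, (T - 1, K, K), "theta")
        _check_sym_psd(self.psi, "random-intercept covariance (psi)")
        _check_sym_psd(self.phi1, "wave-1 deviation covariance (phi1)")
        for w in range(T - 1):
            _check_sym_psd(
                self.theta[w], f"innovation covariance at wave {w + 2} (theta)"
            )
        if not self.is_pair:
            if any(
                getattr(self, a) is not None
                for a in ("psi_cross", "phi1_cross", "theta_cross")
            ):
                raise ValidationError(
                    "cross-twin blocks supplied without between-sibling lags"
                )
            return
        zygs = self.design.groups
        for attr in ("psi_cross", "phi1_cross", "theta_cross"):
            val = getattr(self, attr)
            if val is None or set(val) != set(zygs):
                raise ValidationError(
                    f"{attr} must provide one block per group {zygs}"
                )
        _expect_shape(self.beta_sib, (T - 1, K, K), "beta_sib")
        for z in zygs:
            _expect_shape(self.psi_cross[z], (K, K), f"psi_cross[{z}]")
            _expect_shape(self.phi1_cross[z], (K, K), f"phi1_cross[{z}]")
            _expect_shape(self.theta_cross[z], (T - 1, K, K), f"theta_cross[{z}]")
            for name, blk in (
                (f"cross-twin intercept block ({z})", self.psi_cross[z]),
                (f"cross-twin wave-1 block ({z})", self.phi1_cross[z]),
            ):
                _check_exchange_symmetric(blk, name)
            for w in range(T - 1):
                _check_exchange_symmetric(
                    self.theta_cross[z][w],
                    f"cross-twin innovation block at wave {w + 2} ({z})",
                )
            # joint twin-pair blocks must be valid covariance matrices
            _check_sym_psd(
                _pair_block(self.psi, self.psi_cross[z]),
                f"joint twin-pair intercept covariance for zygosity {z}",
            )
            _check_sym_psd(
                _pair_block(self.phi1, self.phi1_cross[z]),
                f"joint twin-pair wave-1 covariance for zygosity {z}",
            )
            for w in range(T - 1):
                _check_sym_psd(
                    _pair_block(self.theta[w], self.theta_cross[z][w]),
                    f"joint twin-pair innovation covariance at wave {w + 2} "
                    f"for zygosity {z}",
                )

    def marginal_single(self) -> "ParameterSet":
        """Single-person parameter set with the same within-person process."""
        design = PanelDesign(
            self.design.n_traits,
            self.design.n_waves,
            self.design.trait_labels,
            self.design.wave_labels,
            n_siblings=1,
            groups=("all",),
        )
        return ParameterSet(
            design,
            self.mu.copy(),
            self.psi.copy(),
            self.phi1.copy(),
            self.beta.copy(),
            self.theta.copy(),
        )


def _expect_shape(arr: np.ndarray, shape: tuple, name: str) -> None:
    if arr is None or np.shape(arr) != shape:
        raise ValidationError(f"{name} must have shape {shape}")


def _check_sym_psd(mat: np.ndarray, name: str) -> None:
    if not np.allclose(mat, mat.T, atol=1e-8):
        raise ValidationError(f"{name} is not symmetric")
    scale = max(1.0, float(np.max(np.abs(mat))))
    if np.min(np.linalg.eigvalsh(0.5 * (mat + mat.T))) < -_PSD_TOL * scale:
        raise ValidationError(f"{name} is not positive semi-definite")


def _check_exchange_symmetric(blk: np.ndarray, name: str) -> None:
    if not np.allclose(blk, blk.T, atol=1e-8):
        raise ValidationError(
            f"{name} is not symmetric under twin exchange (block != block')"
        )


def _pair_block(within: np.ndarray, cross: np.ndarray) -> np.ndarray:
    return np.block([[within, cross], [cross.T, within]])


# ---------------------------------------------------------------------------
# implied moments
# ---------------------------------------------------------------------------


@lru_cache(maxsize=None)
def _sib_major_perm(T: int, K: int) -> np.ndarray:
    """Map observed (sibling-major) index to wave-major stacked index."""
    perm = np.empty(2 * T * K, dtype=int)
    for s in (0, 1):
        for t in range(T):
            for k in range(K):
                perm[s * T * K + t * K + k] = t * 2 * K + s * K + k
    return perm


def _stack_pair(diag: np.ndarray, off: np.ndarray, transpose_off: bool) -> np.ndarray:
    """2x2 block matrix [[diag, off], [off', diag]] without np.block overhead."""
    m = diag.shape[0]
    out = np.empty((2 * m, 2 * m))
    out[:m, :m] = diag
    out[m:, m:] = diag
    out[:m, m:] = off
    out[m:, :m] = off.T if transpose_off else off
    return out


def _implied_one(
    mats: dict[str, np.ndarray], T: int, K: int, pair: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Mean vector and covariance implied by one group's matrices.

    The deviation covariance is propagated recursively through the lag
    matrices (stacked ``[[beta, sib], [sib, beta]]`` for twin pairs); the
    random-intercept covariance is added to every wave-pair cell.
    """
    if pair:
        phi1 = _stack_pair(mats["phi1"], mats["phi1_c"], True)
        psi = _stack_pair(mats["psi"], mats["psi_c"], True)
        lags = [
            _stack_pair(mats["beta"][w], mats["sib"][w], False)
            for w in range(T - 1)
        ]
        innov = [
            _stack_pair(mats["theta"][w], mats["theta_c"][w], True)
            for w in range(T - 1)
        ]
        m = 2 * K
    else:
        phi1, psi = mats["phi1"], mats["psi"]
        lags = [mats["beta"][w] for w in range(T - 1)]
        innov = [mats["theta"][w] for w in range(T - 1)]
        m = K

    C = np.zeros((T * m, T * m))
    C[:m, :m] = phi1
    for t in range(1, T):
        L = lags[t - 1]
        prev = slice((t - 1) * m, t * m)
        cur = slice(t * m, (t + 1) * m)
        for s in range(t):
            left = slice(s * m, (s + 1) * m)
            blk = L @ C[prev, left]
            C[cur, left] = blk
            C[left, cur] = blk.T
        C[cur, cur] = L @ C[prev, prev] @ L.T + innov[t - 1]

    cov = C + np.tile(psi, (T, T))
    if pair:
        mean = np.concatenate([np.tile(mats["mu"][t], 2) for t in range(T)])
        perm = _sib_major_perm(T, K)
        cov = cov[np.ix_(perm, perm)]
        mean = mean[perm]
    else:
        mean = mats["mu"].reshape(-1)
    return mean, cov


def _group_mats(values: ParameterSet, group: str) -> dict[str, np.ndarray]:
    mats = {
        "mu": values.mu,
        "psi": values.psi,
        "phi1": values.phi1,
        "beta": values.beta,
        "theta": values.theta,
    }
    if values.is_pair:
        mats.update(
            sib=values.beta_sib,
            psi_c=values.psi_cross[group],
            phi1_c=values.phi1_cross[group],
            theta_c=values.theta_cross[group],
        )
    return mats


def parameter_moments(
    values: ParameterSet, validate: bool = True
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-group population mean and covariance implied by ``values``.

    The observed vector is ordered sibling-major: all waves/traits of
    sibling 1, then of sibling 2 (traits fastest).
    """
    if validate:
        values.validate()
    T, K = values.design.n_waves, values.design.n_traits
    out = {}
    for g in values.design.groups:
        mean, cov = _implied_one(_group_mats(values, g), T, K, values.is_pair)
        asym = np.max(np.abs(cov - cov.T))
        if asym > 1e-10:
            raise ValidationError(f"implied covariance asymmetric ({asym:.2e})")
        out[g] = (mean, 0.5 * (cov + cov.T))
    return out


# ---------------------------------------------------------------------------
# symbolic specification
# ---------------------------------------------------------------------------


@dataclass
class Param:
    """One cell of the parameter table.

    ``matrix`` names a block of :class:`ParameterSet` ('mu', 'psi', 'phi1',
    'beta', 'theta', 'sib', 'psi_c', 'phi1_c', 'theta_c'); ``loc`` indexes
    into that block (symmetric blocks carry one entry per lower-triangle
    cell).  ``group`` restricts the cell to one estimation group (``None`` =
    shared across groups).  Free parameters carry an equality-group id
    ``eq``; all cells in one equality group share a single estimated value.
    """

    label: str
    matrix: str
    loc: tuple
    group: str | None = None
    free: bool = True
    value: float = 0.0
    start: float = 0.0
    eq: str | None = None


def _matrix_shapes(design: PanelDesign, kind: str) -> dict[str, tuple]:
    T, K = design.n_waves, design.n_traits
    shapes = {
        "mu": (T, K),
        "psi": (K, K),
        "phi1": (K, K),
        "beta": (T - 1, K, K),
        "theta": (T - 1, K, K),
    }
    if kind == "wf":
        shapes.update(
            sib=(T - 1, K, K),
            psi_c=(K, K),
            phi1_c=(K, K),
            theta_c=(T - 1, K, K),
        )
    return shapes


class ModelSpec:
    """Symbolic (wf-)RI-CLPM specification: parameter table + moment map.

    Instances are treated as immutable; :func:`apply_constraints` returns
    edited copies.  The compiled index arrays that map the free-parameter
    vector onto per-group matrices are cached on first use.
    """

    def __init__(self, design: PanelDesign, kind: str, params: list[Param]):
        if kind not in ("riclpm", "wf"):
            raise DesignError(f"unknown model kind {kind!r}")
        self.design = design
        self.kind = kind
        self.params = params
        self._compiled = None
        seen = set()
        for p in params:
            if p.label in seen:
                raise DesignError(f"duplicate parameter label {p.label!r}")
            seen.add(p.label)

    # -- bookkeeping --------------------------------------------------------

    @property
    def groups(self) -> tuple[str, ...]:
        return self.design.groups

    @property
    def d(self) -> int:
        return self.design.d

    @property
    def free_eq_ids(self) -> list[str]:
        """Distinct equality groups, in order of first appearance."""
        out, seen = [], set()
        for p in self.params:
            if p.free and p.eq not in seen:
                seen.add(p.eq)
                out.append(p.eq)
        return out

    @property
    def n_free(self) -> int:
        return len(self.free_eq_ids)

    @property
    def n_moments(self) -> int:
        """Distinct observed moments (means + covariances) summed over groups."""
        d = self.d
        return len(self.groups) * (d + d * (d + 1) // 2)

    @property
    def df(self) -> int:
        """Model degrees of freedom: observed moments minus free parameters."""
        return self.n_moments - self.n_free

    def copy(self) -> "ModelSpec":
        return ModelSpec(self.design, self.kind, copy.deepcopy(self.params))

    def param(self, label: str) -> Param:
        for p in self.params:
            if p.label == label:
                return p
        raise KeyError(f"no parameter labelled {label!r}")

    def labels(
        self,
        matrix: str | None = None,
        offdiag: bool | None = None,
        free: bool | None = None,
        group: str | None = None,
    ) -> list[str]:
        """Select parameter labels by matrix, trait-diagonality, freeness."""
        out = []
        for p in self.params:
            if matrix is not None and p.matrix != matrix:
                continue
            if free is not None and p.free != free:
                continue
            if group is not None and p.group != group:
                continue
            if offdiag is not None:
                i, j = p.loc[-2], p.loc[-1]
                if (i != j) != offdiag:
                    continue
            out.append(p.label)
        return out

    # -- compiled moment map -------------------------------------------------

    def _compile(self):
        if self._compiled is not None:
            return self._compiled
        eq_index = {eq: i for i, eq in enumerate(self.free_eq_ids)}
        shapes = _matrix_shapes(self.design, self.kind)
        idx = {
            g: {m: -np.ones(s, dtype=int) for m, s in shapes.items()}
            for g in self.groups
        }
        fixed = {
            g: {m: np.zeros(s) for m, s in shapes.items()} for g in self.groups
        }
        for p in self.params:
            targets = self.groups if p.group is None else (p.group,)
            locs = [p.loc]
            if p.matrix in SYMMETRIC_MATRICES and p.loc[-2] != p.loc[-1]:
                swapped = p.loc[:-2] + (p.loc[-1], p.loc[-2])
                locs.append(swapped)
            for g in targets:
                for loc in locs:
                    if p.free:
                        idx[g][p.matrix][loc] = eq_index[p.eq]
                    else:
                        fixed[g][p.matrix][loc] = p.value
        # flatten per group for a single fancy-indexing pass in materialize
        order = list(shapes)
        offsets = {}
        pos = 0
        for m in order:
            size = int(np.prod(shapes[m]))
            offsets[m] = (pos, pos + size, shapes[m])
            pos += size
        flat = {}
        for g in self.groups:
            fidx = np.concatenate([idx[g][m].ravel() for m in order])
            ffix = np.concatenate([fixed[g][m].ravel() for m in order])
            mask = fidx >= 0
            flat[g] = (ffix, np.flatnonzero(mask), fidx[mask])
        self._compiled = (eq_index, idx, fixed, flat, offsets)
        return self._compiled

    def start_vector(self) -> np.ndarray:
        """Tabled start values, one entry per free equality group."""
        starts = {}
        for p in self.params:
            if p.free and p.eq not in starts:
                starts[p.eq] = p.start
        return np.array([starts[eq] for eq in self.free_eq_ids])

    def materialize(self, theta: np.ndarray) -> dict[str, dict[str, np.ndarray]]:
        """Fill per-group parameter matrices from the free-parameter vector."""
        theta = np.asarray(theta, float)
        *_, flat, offsets = self._compile()
        out = {}
        for g in self.groups:
            ffix, where, fidx = flat[g]
            vec = ffix.copy()
            vec[where] = theta[fidx]
            out[g] = {
                m: vec[a:b].reshape(shape) for m, (a, b, shape) in offsets.items()
            }
        return out

    def implied(self, theta: np.ndarray) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per-group implied (mean, covariance) at a free-parameter vector."""
        T, K = self.design.n_waves, self.design.n_traits
        pair = self.kind == "wf"
        mats = self.materialize(theta)
        return {g: _implied_one(mats[g], T, K, pair) for g in self.groups}

    def to_parameter_set(self, theta: np.ndarray) -> ParameterSet:
        """Assemble a :class:`ParameterSet` at a free-parameter vector."""
        mats = self.materialize(theta)
        g0 = self.groups[0]
        if self.kind == "wf":
            return ParameterSet(
                self.design,
                mats[g0]["mu"],
                mats[g0]["psi"],
                mats[g0]["phi1"],
                mats[g0]["beta"],
                mats[g0]["theta"],
                beta_sib=mats[g0]["sib"],
                psi_cross={g: mats[g]["psi_c"] for g in self.groups},
                phi1_cross={g: mats[g]["phi1_c"] for g in self.groups},
                theta_cross={g: mats[g]["theta_c"] for g in self.groups},
            )
        return ParameterSet(
            self.design,
            mats[g0]["mu"],
            mats[g0]["psi"],
            mats[g0]["phi1"],
            mats[g0]["beta"],
            mats[g0]["theta"],
        )

    # -- serialization -------------------------------------------------------

    def parameter_table(self) -> pd.DataFrame:
        """Parameter table as a data frame (one record per parameter cell)."""
        rows = []
        for p in self.params:
            rows.append(
                {
                    "label": p.label,
                    "matrix": p.matrix,
                    "loc": ",".join(str(i) for i in p.loc),
                    "group": "" if p.group is None else p.group,
                    "status": "free" if p.free else f"fixed({p.value:g})",
                    "equality_group": p.eq if p.free else "",
                    "start": p.start,
                }
            )
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.parameter_table().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, design: PanelDesign, kind: str) -> "ModelSpec":
        table = pd.read_csv(path, sep="\t", keep_default_na=False)
        params = []
        for _, r in table.iterrows():
            status = str(r["status"])
            free = status == "free"
            value = 0.0
            if not free:
                value = float(status[len("fixed(") : -1])
            params.append(
                Param(
                    label=str(r["label"]),
                    matrix=str(r["matrix"]),
                    loc=tuple(int(i) for i in str(r["loc"]).split(",")),
                    group=str(r["group"]) or None,
                    free=free,
                    value=value,
                    start=float(r["start"]),
                    eq=str(r["equality_group"]) if free else None,
                )
            )
        return cls(design, kind, params)


def _check_identification(spec: ModelSpec) -> ModelSpec:
    if spec.n_free > spec.n_moments:
        raise IdentificationError(
            f"{spec.n_free} free parameters exceed {spec.n_moments} observed "
            "moments"
        )
    return spec


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------


def _within_person_params(
    design: PanelDesign, time_constrained: bool
) -> list[Param]:
    """Shared within-person parameter cells (means, psi, phi1, beta, theta)."""
    T, K = design.n_waves, design.n_traits
    tl, wl = design.trait_labels, design.wave_labels
    params: list[Param] = []
    for t in range(T):
        for k in range(K):
            lab = f"mu_w{wl[t]}_{tl[k]}"
            params.append(Param(lab, "mu", (t, k), start=0.0, eq=lab))
    for i in range(K):
        for j in range(i + 1):
            lab = f"psi_{tl[i]}_{tl[j]}"
            params.append(
                Param(lab, "psi", (i, j), start=0.5 if i == j else 0.0, eq=lab)
            )
    for i in range(K):
        for j in range(i + 1):
            lab = f"phi1_{tl[i]}_{tl[j]}"
            params.append(
                Param(lab, "phi1", (i, j), start=0.5 if i == j else 0.0, eq=lab)
            )
    for w in range(T - 1):
        for i in range(K):
            for j in range(K):
                lab = f"beta_w{wl[w + 1]}_{tl[i]}_{tl[j]}"
                eq = f"beta_w{wl[1]}_{tl[i]}_{tl[j]}" if time_constrained else lab
                params.append(
                    Param(lab, "beta", (w, i, j), start=0.1 if i == j else 0.0, eq=eq)
                )
    for w in range(T - 1):
        for i in range(K):
            for j in range(i + 1):
                lab = f"theta_w{wl[w + 1]}_{tl[i]}_{tl[j]}"
                eq = f"theta_w{wl[1]}_{tl[i]}_{tl[j]}" if time_constrained else lab
                params.append(
                    Param(
                        lab, "theta", (w, i, j), start=0.5 if i == j else 0.0, eq=eq
                    )
                )
    return params


def build_riclpm(design: PanelDesign, time_constrained: bool = False) -> ModelSpec:
    """Single-person RI-CLPM specification.

    The unconstrained variant frees all wave/trait means, random-intercept
    (co)variances, wave-1 deviation (co)variances, lag coefficients and
    innovation (co)variances.  ``time_constrained=True`` additionally equates
    each lag coefficient and each innovation (co)variance across waves (one
    equality group per cell position spanning all lags).
    """
    if design.n_siblings != 1:
        raise DesignError("build_riclpm requires n_siblings = 1")
    params = _within_person_params(design, time_constrained)
    return _check_identification(ModelSpec(design, "riclpm", params))


def build_wf_riclpm(design: PanelDesign) -> ModelSpec:
    """Within-family RI-CLPM for MZ/DZ twin pairs.

    Within-person parameters are shared across both twins and both zygosity
    groups; cross-twin covariance blocks are free per zygosity with
    twin-exchange symmetry; between-sibling lag matrices are shared across
    zygosity and across direction.
    """
    if design.n_siblings != 2:
        raise DesignError("build_wf_riclpm requires n_siblings = 2")
    if set(design.groups) != {"MZ", "DZ"}:
        raise DesignError("wf-RI-CLPM groups must be exactly {MZ, DZ}")
    T, K = design.n_waves, design.n_traits
    tl, wl = design.trait_labels, design.wave_labels
    params = _within_person_params(design, time_constrained=False)
    for w in range(T - 1):
        for i in range(K):
            for j in range(K):
                lab = f"sib_w{wl[w + 1]}_{tl[i]}_{tl[j]}"
                params.append(Param(lab, "sib", (w, i, j), start=0.0, eq=lab))
    for z in design.groups:
        start_scale = 0.5 if z == "MZ" else 0.25
        for i in range(K):
            for j in range(i + 1):
                lab = f"psi_c_{tl[i]}_{tl[j]}_{z}"
                params.append(
                    Param(
                        lab,
                        "psi_c",
                        (i, j),
                        group=z,
                        start=0.5 * start_scale if i == j else 0.0,
                        eq=lab,
                    )
                )
        for i in range(K):
            for j in range(i + 1):
                lab = f"phi1_c_{tl[i]}_{tl[j]}_{z}"
                params.append(
                    Param(
                        lab,
                        "phi1_c",
                        (i, j),
                        group=z,
                        start=0.25 * start_scale if i == j else 0.0,
                        eq=lab,
                    )
                )
        for w in range(T - 1):
            for i in range(K):
                for j in range(i + 1):
                    lab = f"theta_c_w{wl[w + 1]}_{tl[i]}_{tl[j]}_{z}"
                    params.append(
                        Param(
                            lab,
                            "theta_c",
                            (w, i, j),
                            group=z,
                            start=0.25 * start_scale if i == j else 0.0,
                            eq=lab,
                        )
                    )
    return _check_identification(ModelSpec(design, "wf", params))


def implied_moments(
    spec: ModelSpec, values: ParameterSet
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-group implied mean vector and covariance at explicit values.

    ``values`` must satisfy the :class:`ParameterSet` invariants (validated);
    the result is symmetric to within 1e-10 by construction of the recursive
    moment map.
    """
    if (spec.kind == "wf") != values.is_pair:
        raise ValidationError("parameter set does not match the model kind")
    if values.design.n_waves != spec.design.n_waves or (
        values.design.n_traits != spec.design.n_traits
    ):
        raise ValidationError("parameter set design does not match the spec")
    return parameter_moments(values)


# ---------------------------------------------------------------------------
# constraint edits
# ---------------------------------------------------------------------------


def apply_constraints(spec: ModelSpec, edits: Iterable[dict]) -> ModelSpec:
    """Return a new spec with pruning/equality/multi-group edits applied.

    Each edit is a mapping with exactly one of:

    ``{"fix": label, "value": v}``
        Fix the labelled parameter (and every parameter sharing its equality
        group) to ``v`` (default 0).  Re-fixing to a different value raises
        :class:`ConstraintConflictError`.
    ``{"merge": [label, ...]}``
        Place the labelled free parameters into one equality group.
    ``{"split_by_group": label}``
        Replace a group-shared parameter by per-group copies, each with its
        own equality group (labels suffixed ``_<group>``).
    """
    new = spec.copy()
    by_label = {p.label: p for p in new.params}

    def _eq_members(eq: str) -> list[Param]:
        return [p for p in new.params if p.free and p.eq == eq]

    for edit in edits:
        if "fix" in edit:
            label = edit["fix"]
            value = float(edit.get("value", 0.0))
            if label not in by_label:
                raise KeyError(f"no parameter labelled {label!r}")
            p = by_label[label]
            if not p.free:
                if p.value != value:
                    raise ConstraintConflictError(
                        f"{label} already fixed to {p.value}, cannot refix to "
                        f"{value}"
                    )
                continue
            for member in _eq_members(p.eq):
                member.free = False
                member.value = value
                member.eq = None
        elif "merge" in edit:
            labels = list(edit["merge"])
            if not labels:
                continue
            for lab in labels:
                if lab not in by_label:
                    raise KeyError(f"no parameter labelled {lab!r}")
                if not by_label[lab].free:
                    raise ConstraintConflictError(
                        f"cannot merge fixed parameter {lab}"
                    )
            target_eq = by_label[labels[0]].eq
            for lab in labels[1:]:
                by_label[lab].eq = target_eq
        elif "split_by_group" in edit:
            label = edit["split_by_group"]
            if label not in by_label:
                raise KeyError(f"no parameter labelled {label!r}")
            p = by_label[label]
            if p.group is not None:
                continue  # already group-specific
            pos = new.params.index(p)
            copies = []
            for g in new.groups:
                q = copy.deepcopy(p)
                q.label = f"{label}_{g}"
                q.group = g
                if q.free:
                    q.eq = f"{p.eq}_{g}"
                copies.append(q)
            new.params[pos : pos + 1] = copies
            del by_label[label]
            for q in copies:
                by_label[q.label] = q
        else:
            raise ValueError(f"unrecognized edit {edit!r}")
    return _check_identification(ModelSpec(new.design, new.kind, new.params))
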