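"""Maximum-likelihood estimation of (wf-)RI-CLPM specifications.

Two likelihood forms are available, both based on the multivariate-normal
model implied by a :class:`~riclpm.model_builder.ModelSpec`:

* a *moment* form operating on per-group sample means/covariances (the
  classical ML discrepancy; exact for complete data), and
* a *casewise* full-information (FIML) form that accommodates arbitrary
  missing-data patterns, with the saturated model fitted by an EM algorithm
  so the chi-square statistic remains comparable.

Optimization is quasi-Newton (L-BFGS) over the unconstrained free-parameter
vector, with equality groups resolved by substitution, followed by Newton
polishing steps using a finite-difference Hessian.  Covariance-block
positive definiteness is not hard-enforced: Heywood-style solutions are
permitted (steps yielding a non-invertible implied covariance are rejected
during the line search).  Standard errors come from the inverse observed
information; robust (sandwich/scaled) corrections are not implemented.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.linalg as sla
from scipy.optimize import minimize
from scipy.stats import chi2, norm

from .model_builder import ModelSpec, ValidationError

__all__ = ["FitResult", "fit", "fit_indices", "standard_errors", "em_mvnorm"]

_BIG = 1e10
_LOG2PI = np.log(2.0 * np.pi)


# ---------------------------------------------------------------------------
# objectives
# ---------------------------------------------------------------------------


class _MomentObjective:
    """Per-observation ML discrepancy F(theta) from per-group (mean, cov, n).

    At the saturated solution F = 0; the model chi-square is N * F_min.
    """

    def __init__(self, spec: ModelSpec, stats: dict[str, tuple]):
        self.spec = spec
        self.groups = []
        for g in spec.groups:
            m, S, n = stats[g]
            sign, logdetS = np.linalg.slogdet(S)
            if sign <= 0:
                raise ValidationError(
                    f"sample covariance for group {g} is singular; "
                    "use the casewise (FIML) form or more data"
                )
            self.groups.append((g, np.asarray(m, float), np.asarray(S, float),
                                float(n), logdetS))
        self.N = sum(n for *_, n, _ in self.groups)
        self.d = spec.d

    def __call__(self, theta: np.ndarray) -> float:
        try:
            implied = self.spec.implied(theta)
        except Exception:
            return _BIG
        total = 0.0
        for g, m, S, n, logdetS in self.groups:
            mean, Sigma = implied[g]
            try:
                c = sla.cho_factor(Sigma, lower=True, check_finite=False)
            except sla.LinAlgError:
                return _BIG
            logdet = 2.0 * np.sum(np.log(np.diag(c[0])))
            if not np.isfinite(logdet):
                return _BIG
            X = sla.cho_solve(c, S, check_finite=False)
            r = m - mean
            quad = float(r @ sla.cho_solve(c, r, check_finite=False))
            Fg = logdet - logdetS + np.trace(X) + quad - self.d
            total += (n / self.N) * Fg
        if not np.isfinite(total):
            return _BIG
        return total

    def loglik_saturated(self) -> float:
        ll = 0.0
        for g, m, S, n, logdetS in self.groups:
            ll += -0.5 * n * (self.d * _LOG2PI + logdetS + self.d)
        return ll

    def loglik(self, fmin: float) -> float:
        return self.loglik_saturated() - 0.5 * self.N * fmin

    def baseline_chi_square(self) -> tuple[float, int]:
        """Independence model (free means/variances, zero covariances)."""
        chi_b = 0.0
        for g, m, S, n, logdetS in self.groups:
            chi_b += n * (np.sum(np.log(np.diag(S))) - logdetS)
        n_free_b = 2 * self.d * len(self.groups)
        df_b = self.spec.n_moments - n_free_b
        return chi_b, df_b

    def sample_moments(self) -> dict[str, tuple[np.ndarray, np.ndarray, float]]:
        return {g: (m, S, n) for g, m, S, n, _ in self.groups}


class _FIMLObjective:
    """Casewise -2 loglik / N with missing-pattern grouping."""

    def __init__(self, spec: ModelSpec, data: dict[str, np.ndarray]):
        self.spec = spec
        self.groups = []
        self.N = 0.0
        for g in spec.groups:
            X = np.asarray(data[g], float)
            keep = np.isfinite(X).any(axis=1)
            if keep.sum() < len(X):
                warnings.warn(
                    f"dropping {len(X) - keep.sum()} all-missing rows in "
                    f"group {g}"
                )
            X = X[keep]
            patterns = _split_patterns(X)
            self.groups.append((g, patterns, len(X)))
            self.N += len(X)

    def __call__(self, theta: np.ndarray) -> float:
        try:
            implied = self.spec.implied(theta)
        except Exception:
            return _BIG
        total = 0.0
        for g, patterns, _ in self.groups:
            mean, Sigma = implied[g]
            ll = _pattern_loglik(patterns, mean, Sigma)
            if ll is None:
                return _BIG
            total += ll
        if not np.isfinite(total):
            return _BIG
        return -2.0 * total / self.N

    def loglik(self, fmin: float) -> float:
        return -0.5 * self.N * fmin

    def loglik_saturated(self) -> float:
        ll = 0.0
        self._em = {}
        for g, patterns, n in self.groups:
            mu, Sigma, ll_g = em_mvnorm_patterns(patterns, self.spec.d)
            self._em[g] = (mu, Sigma, n)
            ll += ll_g
        return ll

    def baseline_chi_square(self) -> tuple[float, int]:
        ll_b = 0.0
        for g, patterns, _ in self.groups:
            # per-variable observed-case univariate ML
            col_vals: dict[int, list[np.ndarray]] = {}
            for cols, rows in patterns:
                for j, c in enumerate(cols):
                    col_vals.setdefault(c, []).append(rows[:, j])
            for c, chunks in col_vals.items():
                v = np.concatenate(chunks)
                var = max(v.var(), 1e-300)
                ll_b += -0.5 * (len(v) * (_LOG2PI + np.log(var)) + len(v))
        ll_sat = getattr(self, "_em", None)
        if ll_sat is None:
            raise RuntimeError("call loglik_saturated first")
        ll_sat_val = sum(
            _pattern_loglik(patterns, self._em[g][0], self._em[g][1])
            for g, patterns, _ in self.groups
        )
        chi_b = 2.0 * (ll_sat_val - ll_b)
        n_free_b = 2 * self.spec.d * len(self.groups)
        df_b = self.spec.n_moments - n_free_b
        return chi_b, df_b

    def sample_moments(self) -> dict[str, tuple[np.ndarray, np.ndarray, float]]:
        """EM-estimated saturated moments per group (requires loglik_saturated)."""
        if not hasattr(self, "_em"):
            self.loglik_saturated()
        return dict(self._em)


def _split_patterns(X: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
    """Group rows of ``X`` by missingness pattern: [(obs_cols, values), ...]."""
    obs = np.isfinite(X)
    order = np.lexsort(obs.T[::-1])
    Xo, obso = X[order], obs[order]
    out = []
    start = 0
    for i in range(1, len(Xo) + 1):
        if i == len(Xo) or not np.array_equal(obso[i], obso[start]):
            cols = np.flatnonzero(obso[start])
            out.append((cols, Xo[start:i][:, cols]))
            start = i
    return out


def _pattern_loglik(patterns, mean, Sigma) -> float | None:
    total = 0.0
    for cols, rows in patterns:
        sub = Sigma[np.ix_(cols, cols)]
        try:
            c = sla.cho_factor(sub, lower=True, check_finite=False)
        except sla.LinAlgError:
            return None
        logdet = 2.0 * np.sum(np.log(np.diag(c[0])))
        R = rows - mean[cols]
        quad = float(np.sum(R * sla.cho_solve(c, R.T, check_finite=False).T))
        total += -0.5 * (len(rows) * (len(cols) * _LOG2PI + logdet) + quad)
    return total


def em_mvnorm_patterns(patterns, d: int, max_iter: int = 2000, tol: float = 1e-10):
    """EM for an unstructured MVN mean/covariance with missing data.

    Operates on pattern-grouped data as produced by :func:`_split_patterns`;
    returns (mu, Sigma, loglik) at convergence.  Used for the saturated
    model under FIML.
    """
    n = sum(len(rows) for _, rows in patterns)
    mu = np.zeros(d)
    counts = np.zeros(d)
    for cols, rows in patterns:
        mu[cols] += rows.sum(axis=0)
        counts[cols] += len(rows)
    mu = mu / np.maximum(counts, 1)
    var = np.full(d, 1e-6)
    for cols, rows in patterns:
        var[cols] += ((rows - mu[cols]) ** 2).sum(axis=0) / np.maximum(
            counts[cols], 1
        )
    Sigma = np.diag(var)
    last = -np.inf
    for _ in range(max_iter):
        S1 = np.zeros(d)
        S2 = np.zeros((d, d))
        for cols, rows in patterns:
            miss = np.setdiff1d(np.arange(d), cols, assume_unique=True)
            Soo = Sigma[np.ix_(cols, cols)]
            c = sla.cho_factor(Soo, lower=True, check_finite=False)
            R = rows - mu[cols]
            if len(miss):
                Smo = Sigma[np.ix_(miss, cols)]
                W = sla.cho_solve(c, Smo.T, check_finite=False).T  # (m, o)
                Em = mu[miss] + R @ W.T
                Cond = Sigma[np.ix_(miss, miss)] - W @ Smo.T
            full = np.zeros((len(rows), d))
            full[:, cols] = rows
            if len(miss):
                full[:, miss] = Em
            S1 += full.sum(axis=0)
            S2 += full.T @ full
            if len(miss):
                S2[np.ix_(miss, miss)] += len(rows) * Cond
        mu = S1 / n
        Sigma = S2 / n - np.outer(mu, mu)
        Sigma = 0.5 * (Sigma + Sigma.T)
        ll = _pattern_loglik(patterns, mu, Sigma)
        if ll is None:
            break
        if abs(ll - last) < tol * (1.0 + abs(ll)):
            last = ll
            break
        last = ll
    return mu, Sigma, last


#  convenience wrapper used directly in tests / by callers with raw arrays
def em_mvnorm(X: np.ndarray, **kwargs):
    """EM estimate of MVN mean/covariance from a raw (n, d) matrix with NaN."""
    X = np.asarray(X, float)
    return em_mvnorm_patterns(_split_patterns(X), X.shape[1], **kwargs)


# ---------------------------------------------------------------------------
# start values
# ---------------------------------------------------------------------------


def _available_moments(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    df = pd.DataFrame(X)
    m = df.mean().to_numpy()
    S = df.cov(min_periods=2).to_numpy()
    S = np.where(np.isfinite(S), S, 0.0)
    m = np.where(np.isfinite(m), m, 0.0)
    return m, S, float(np.isfinite(X).any(axis=1).sum())


def _start_vector(spec: ModelSpec, stats: dict[str, tuple]) -> np.ndarray:
    """Moment-based start values (means from sample means, intercept
    variances from cross-wave covariances, lags 0.1, innovations from the
    residual variance split); falls back to tabled starts elsewhere."""
    T, K = spec.design.n_waves, spec.design.n_traits
    n_sib = spec.design.n_siblings

    def col(s, t, k):
        return s * T * K + t * K + k

    ns = np.array([stats[g][2] for g in spec.groups], float)
    wts = ns / ns.sum() if ns.sum() > 0 else np.full(len(ns), 1.0 / len(ns))
    m_avg = sum(w * stats[g][0] for w, g in zip(wts, spec.groups))
    S_avg = sum(w * stats[g][1] for w, g in zip(wts, spec.groups))

    def psi_ii(i, S):
        vals = [
            S[col(s, t, i), col(s, u, i)]
            for s in range(n_sib)
            for t in range(T)
            for u in range(T)
            if t != u
        ]
        v_mean = np.mean([S[col(s, t, i), col(s, t, i)] for s in range(n_sib)
                          for t in range(T)])
        lo = 0.05 * max(v_mean, 1e-3)
        return float(np.clip(np.mean(vals), lo, max(v_mean, lo)))

    def var_at(i, t, S):
        return float(
            np.mean([S[col(s, t, i), col(s, t, i)] for s in range(n_sib)])
        )

    eq_first = {}
    for p in spec.params:
        if p.free and p.eq not in eq_first:
            eq_first[p.eq] = p

    out = []
    for eq in spec.free_eq_ids:
        p = eq_first[eq]
        if p.group is not None and p.group in stats and p.matrix in (
            "mu", "psi", "phi1", "beta", "theta"
        ):
            m_use, S_use = stats[p.group][0], stats[p.group][1]
        else:
            m_use, S_use = m_avg, S_avg
        mat, loc = p.matrix, p.loc
        if mat == "mu":
            t, k = loc
            out.append(float(np.mean([m_use[col(s, t, k)] for s in range(n_sib)])))
        elif mat == "psi":
            i, j = loc
            out.append(psi_ii(i, S_use) if i == j else 0.0)
        elif mat == "phi1":
            i, j = loc
            if i == j:
                v = var_at(i, 0, S_use) - psi_ii(i, S_use)
                out.append(float(np.clip(v, 0.05, None)))
            else:
                out.append(0.0)
        elif mat == "beta":
            i, j = loc[-2], loc[-1]
            out.append(0.1 if i == j else 0.0)
        elif mat == "sib":
            out.append(0.0)
        elif mat == "theta":
            w, i, j = loc
            if i == j:
                v = 0.8 * (var_at(i, w + 1, S_use) - psi_ii(i, S_use))
                out.append(float(np.clip(v, 0.05, None)))
            else:
                out.append(0.0)
        elif mat in ("psi_c", "phi1_c", "theta_c"):
            z = p.group
            S_g = stats[z][1] if z in stats else S_avg
            if mat == "psi_c":
                i, j = loc
                if i == j:
                    vals = [
                        S_g[col(0, t, i), col(1, u, i)]
                        for t in range(T)
                        for u in range(T)
                        if t != u
                    ]
                    cap = 0.9 * psi_ii(i, S_avg)
                    out.append(float(np.clip(np.mean(vals), -cap, cap)))
                else:
                    out.append(0.0)
            elif mat == "phi1_c":
                i, j = loc
                out.append(0.0)
            else:  # theta_c
                w, i, j = loc
                if i == j:
                    raw = S_g[col(0, w + 1, i), col(1, w + 1, i)]
                    psi_c = np.mean(
                        [S_g[col(0, t, i), col(1, u, i)]
                         for t in range(T) for u in range(T) if t != u]
                    )
                    cap = 0.9 * max(
                        0.8 * (var_at(i, w + 1, S_avg) - psi_ii(i, S_avg)), 0.05
                    )
                    out.append(float(np.clip(0.8 * (raw - psi_c), -cap, cap)))
                else:
                    out.append(0.0)
        else:
            out.append(p.start)
    return np.asarray(out)


# ---------------------------------------------------------------------------
# numerical derivatives
# ---------------------------------------------------------------------------


def _fd_grad(f, x: np.ndarray, rel: float = 1e-6) -> np.ndarray:
    g = np.empty_like(x)
    for i in range(len(x)):
        h = rel * max(1.0, abs(x[i]))
        xp, xm = x.copy(), x.copy()
        xp[i] += h
        xm[i] -= h
        g[i] = (f(xp) - f(xm)) / (2.0 * h)
    return g


def _fd_hess(f, x: np.ndarray, rel: float = 1e-4) -> np.ndarray:
    p = len(x)
    h = rel * np.maximum(1.0, np.abs(x))
    H = np.empty((p, p))
    f0 = f(x)
    fp = np.empty(p)
    fm = np.empty(p)
    for i in range(p):
        xp, xm = x.copy(), x.copy()
        xp[i] += h[i]
        xm[i] -= h[i]
        fp[i] = f(xp)
        fm[i] = f(xm)
        H[i, i] = (fp[i] + fm[i] - 2.0 * f0) / h[i] ** 2
    for i in range(p):
        for j in range(i):
            xpp, xpm, xmp, xmm = x.copy(), x.copy(), x.copy(), x.copy()
            xpp[i] += h[i]; xpp[j] += h[j]
            xpm[i] += h[i]; xpm[j] -= h[j]
            xmp[i] -= h[i]; xmp[j] += h[j]
            xmm[i] -= h[i]; xmm[j] -= h[j]
            H[i, j] = H[j, i] = (
                f(xpp) - f(xpm) - f(xmp) + f(xmm)
            ) / (4.0 * h[i] * h[j])
    return H


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """Estimates, fit statistics and diagnostics of one fitted model."""

    spec: ModelSpec
    method: str
    theta: np.ndarray
    estimates: dict[str, float]
    se: dict[str, float] | None
    vcov: np.ndarray | None
    loglik: float
    loglik_sat: float
    chi_square: float
    df: int
    p_value: float
    aic: float
    bic: float
    rmsea: float
    srmr: float
    cfi: float
    n_per_group: dict[str, float]
    N: float
    converged: bool
    grad_norm: float
    n_iter: int
    messages: list[str] = field(default_factory=list)
    _objective: object = field(default=None, repr=False)

    @property
    def n_groups(self) -> int:
        return len(self.n_per_group)

    def parameter_set(self):
        """Parameter values at the estimates as a ParameterSet."""
        return self.spec.to_parameter_set(self.theta)

    def wald_table(self, labels: list[str] | None = None) -> pd.DataFrame:
        """Wald z-tests (estimate / SE) for free parameters."""
        if self.se is None:
            raise ValidationError(
                "standard errors unavailable (information matrix not "
                "positive definite)"
            )
        if labels is None:
            labels = self.spec.free_eq_ids
        eq_of = {p.label: p.eq for p in self.spec.params if p.free}
        rows = []
        for lab in labels:
            eq = eq_of.get(lab, lab)
            est, se = self.estimates[eq], self.se[eq]
            z = est / se if se > 0 else np.nan
            rows.append(
                {
                    "label": lab,
                    "estimate": est,
                    "se": se,
                    "z": z,
                    "p": 2.0 * norm.sf(abs(z)) if np.isfinite(z) else np.nan,
                }
            )
        return pd.DataFrame(rows)

    def summary_frame(self) -> pd.DataFrame:
        table = self.spec.parameter_table()
        est, ses = [], []
        for _, r in table.iterrows():
            eq = r["equality_group"]
            if eq:
                est.append(self.estimates[eq])
                ses.append(self.se[eq] if self.se else np.nan)
            else:
                est.append(float(str(r["status"])[len("fixed("):-1]))
                ses.append(np.nan)
        table["estimate"] = est
        table["se"] = ses
        return table

    def write_report(self, path) -> None:
        """Structured plain-text report: parameter table plus fit indices."""
        with open(path, "w") as fh:
            fh.write(f"# model: {self.spec.kind}  method: {self.method}\n")
            fh.write(
                f"# N: {self.N:g}  groups: "
                + ", ".join(f"{g}={n:g}" for g, n in self.n_per_group.items())
                + "\n"
            )
            fh.write(
                f"# loglik: {self.loglik:.6f}  chi2: {self.chi_square:.6f}  "
                f"df: {self.df}  p: {self.p_value:.4g}\n"
            )
            fh.write(
                f"# AIC: {self.aic:.3f}  BIC: {self.bic:.3f}  "
                f"RMSEA: {self.rmsea:.4f}  SRMR: {self.srmr:.4f}  "
                f"CFI: {self.cfi:.4f}\n"
            )
            fh.write(f"# converged: {self.converged}\n")
            self.summary_frame().to_csv(fh, sep="\t", index=False)


@dataclass
class _Baseline:
    chi_square: float
    df: int


def fit_indices(result, baseline) -> dict[str, float]:
    """RMSEA / CFI from a fitted model and its independence baseline.

    RMSEA uses the multi-group convention
    ``sqrt(G) * sqrt(max(chi2 - df, 0) / (df * N))`` and is defined as 0
    when df = 0; CFI is ``1 - max(chi2 - df, 0) / max(chi2_b - df_b,
    chi2 - df, 0)`` (1 when the denominator vanishes).
    """
    chi_sq, df = result.chi_square, result.df
    if df > 0:
        rmsea = np.sqrt(result.n_groups) * np.sqrt(
            max(chi_sq - df, 0.0) / (df * result.N)
        )
    else:
        rmsea = 0.0
    num = max(chi_sq - df, 0.0)
    den = max(baseline.chi_square - baseline.df, chi_sq - df, 0.0)
    cfi = 1.0 - num / den if den > 0 else 1.0
    return {"rmsea": float(rmsea), "cfi": float(min(max(cfi, 0.0), 1.0))}


def _srmr(spec, implied, sample) -> float:
    total, wsum = 0.0, 0.0
    for g in spec.groups:
        mean, Sigma = implied[g]
        m, S, n = sample[g]
        sd = np.sqrt(np.clip(np.diag(S), 1e-300, None))
        R = (S - Sigma) / np.outer(sd, sd)
        tri = R[np.tril_indices_from(R)]
        total += n * np.mean(tri**2)
        wsum += n
    return float(np.sqrt(total / wsum))


# ---------------------------------------------------------------------------
# main entry point
# ---------------------------------------------------------------------------


def fit(
    spec: ModelSpec,
    data,
    method: str = "auto",
    se: bool = True,
    start: np.ndarray | None = None,
    options: Mapping | None = None,
) -> FitResult:
    """Fit a model specification by maximum likelihood.

    Parameters
    ----------
    spec
        Model specification from :mod:`riclpm.model_builder`.
    data
        One of: a :class:`~riclpm.data_io.TwinDataset`; a mapping
        ``{group: (n, d) array}`` with NaN for missing values; or a mapping
        ``{group: (mean, cov, n)}`` of per-group sample moments.
    method
        'moment', 'fiml', or 'auto' (moment form when data are complete or
        given as moments, casewise FIML otherwise).
    se
        Compute observed-information standard errors (finite-difference
        Hessian at the optimum).
    start
        Optional start vector overriding the moment-based defaults.
    """
    opts = dict(options or {})
    arrays, stats = _coerce_data(spec, data)
    messages: list[str] = []

    if method == "auto":
        complete = arrays is None or all(
            np.isfinite(X).all() for X in arrays.values()
        )
        method = "moment" if complete else "fiml"
    if method == "moment" and stats is None:
        stats = {
            g: _sample_mean_cov(arrays[g]) for g in spec.groups
        }
    if method == "fiml" and arrays is None:
        raise ValidationError("FIML requires casewise data, not moments")

    if stats is None:
        stats = {g: _available_moments(arrays[g]) for g in spec.groups}
    n_per_group = {g: float(stats[g][2]) for g in spec.groups}
    N = sum(n_per_group.values())
    for g, n in n_per_group.items():
        if n <= spec.n_free:
            warnings.warn(
                f"group {g} has n={n:g} <= {spec.n_free} free parameters"
            )

    objective = (
        _MomentObjective(spec, stats)
        if method == "moment"
        else _FIMLObjective(spec, arrays)
    )

    x0 = np.asarray(start, float) if start is not None else _start_vector(spec, stats)
    if not np.isfinite(objective(x0)):
        x0 = spec.start_vector()

    res = minimize(
        objective,
        x0,
        method="L-BFGS-B",
        options=dict(
            maxiter=opts.get("maxiter", 20000),
            maxfun=opts.get("maxfun", 2_000_000),
            ftol=opts.get("ftol", 1e-11),
            gtol=opts.get("gtol", 1e-9),
        ),
    )
    x = res.x
    n_iter = int(res.nit)

    # Newton polish with a finite-difference Hessian (reused for SEs)
    x_lbfgs = x.copy()
    H = _fd_hess(objective, x)
    for _ in range(opts.get("polish", 4)):
        g = _fd_grad(objective, x)
        try:
            cH = sla.cho_factor(H, check_finite=False)
            step = -sla.cho_solve(cH, g, check_finite=False)
        except sla.LinAlgError:
            break
        f0 = objective(x)
        t = 1.0
        accepted = False
        while t > 1e-6:
            cand = x + t * step
            if objective(cand) < f0:
                x = cand
                accepted = True
                break
            t *= 0.5
        if not accepted:
            break
        if np.linalg.norm(g) < 1e-11:
            break
    grad = _fd_grad(objective, x)
    grad_norm = float(np.linalg.norm(grad, np.inf))
    gtol_conv = opts.get("convergence_grad_tol", 1e-5)
    converged = bool(res.success or grad_norm < gtol_conv)
    if not converged:
        messages.append(
            f"optimizer did not converge (gradient norm {grad_norm:.3g})"
        )

    fmin = objective(x)
    ll_sat = objective.loglik_saturated()
    ll = objective.loglik(fmin)
    chi_sq = max(2.0 * (ll_sat - ll), 0.0)
    df = spec.df
    p_value = float(chi2.sf(chi_sq, df)) if df > 0 else 1.0
    k = spec.n_free
    aic = -2.0 * ll + 2.0 * k
    bic = -2.0 * ll + np.log(N) * k
    chi_b, df_b = objective.baseline_chi_square()

    implied = spec.implied(x)
    sample = objective.sample_moments()
    srmr = _srmr(spec, implied, sample)

    est = dict(zip(spec.free_eq_ids, x))
    se_dict, vcov = None, None
    if se:
        # observed information = Hessian of -loglik = (N/2) * Hessian(objective);
        # the polish Hessian is reused unless the polish moved the estimates
        if np.max(np.abs(x - x_lbfgs)) > 1e-3:
            H = _fd_hess(objective, x)
        info = 0.5 * N * H
        try:
            cI = sla.cho_factor(info, check_finite=False)
            vcov = sla.cho_solve(cI, np.eye(len(x)), check_finite=False)
            se_dict = dict(zip(spec.free_eq_ids, np.sqrt(np.diag(vcov))))
        except (sla.LinAlgError, FloatingPointError):
            messages.append(
                "observed information not positive definite; standard errors "
                "not reported"
            )
            warnings.warn(messages[-1])

    result = FitResult(
        spec=spec,
        method=method,
        theta=x,
        estimates=est,
        se=se_dict,
        vcov=vcov,
        loglik=float(ll),
        loglik_sat=float(ll_sat),
        chi_square=float(chi_sq),
        df=df,
        p_value=p_value,
        aic=float(aic),
        bic=float(bic),
        rmsea=np.nan,
        srmr=srmr,
        cfi=np.nan,
        n_per_group=n_per_group,
        N=float(N),
        converged=converged,
        grad_norm=grad_norm,
        n_iter=n_iter,
        messages=messages,
        _objective=objective,
    )
    idx = fit_indices(result, _Baseline(chi_b, df_b))
    result.rmsea = idx["rmsea"]
    result.cfi = idx["cfi"]
    return result


def standard_errors(fit_result: FitResult) -> dict[str, float]:
    """Observed-information standard errors of a converged fit."""
    if fit_result.se is not None:
        return fit_result.se
    if fit_result._objective is None:
        raise ValidationError("fit carries no objective; refit with se=True")
    H = _fd_hess(fit_result._objective, fit_result.theta)
    info = 0.5 * fit_result.N * H
    cI = sla.cho_factor(info, check_finite=False)
    vcov = sla.cho_solve(cI, np.eye(len(fit_result.theta)), check_finite=False)
    fit_result.vcov = vcov
    fit_result.se = dict(
        zip(fit_result.spec.free_eq_ids, np.sqrt(np.diag(vcov)))
    )
    return fit_result.se


def _sample_mean_cov(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    X = np.asarray(X, float)
    n = len(X)
    m = X.mean(axis=0)
    D = X - m
    S = D.T @ D / n  # ML (biased) covariance
    return m, S, float(n)


def _coerce_data(spec: ModelSpec, data):
    """Normalize input into (arrays | None, stats | None)."""
    from .data_io import TwinDataset

    if isinstance(data, TwinDataset):
        by = None
        if spec.kind == "wf":
            by = "zygosity"
        elif len(spec.groups) > 1:
            by = "sex" if set(spec.groups) != {"all"} else None
        arrays = data.group_arrays(by)
        missing = [g for g in spec.groups if g not in arrays]
        if missing:
            raise ValidationError(f"data lack groups {missing}")
        return {g: arrays[g] for g in spec.groups}, None
    if isinstance(data, Mapping):
        missing = [g for g in spec.groups if g not in data]
        if missing:
            raise ValidationError(f"data lack groups {missing}")
        first = data[spec.groups[0]]
        if isinstance(first, tuple) and len(first) == 3:
            stats = {}
            for g in spec.groups:
                m, S, n = data[g]
                m, S = np.asarray(m, float), np.asarray(S, float)
                if m.shape != (spec.d,) or S.shape != (spec.d, spec.d):
                    raise ValidationError(
                        f"moments for group {g} do not match d={spec.d}"
                    )
                stats[g] = (m, S, float(n))
            return None, stats
        arrays = {}
        for g in spec.groups:
            X = np.asarray(data[g], float)
            if X.ndim != 2 or X.shape[1] != spec.d:
                raise ValidationError(
                    f"data for group {g} must be (n, {spec.d})"
                )
            arrays[g] = X
        return arrays, None
    raise TypeError("data must be a TwinDataset, per-group arrays, or moments")
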