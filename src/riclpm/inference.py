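"""Nested model comparison, FDR pruning, and multi-group sex tests.

Implements the full -> pruned -> null workflow: path-level p-values from
Wald statistics of the fitted full model, Benjamini-Hochberg (or nominal)
selection over the scoped family of paths, a single joint refit of the
pruned model, and likelihood-ratio comparisons across the nested sequence.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .estimator import FitResult, fit
from .model_builder import ModelSpec, apply_constraints

__all__ = [
    "ComparisonTable",
    "PruneResult",
    "lr_test",
    "bh_fdr",
    "prune_and_compare",
    "sex_multigroup_test",
    "edge_list",
]

logger = logging.getLogger("riclpm")

PATH_SCOPES = ("within_person_cross_lags", "between_sibling_paths")


@dataclass
class ComparisonTable:
    """Fit summary per model plus likelihood-ratio tests per adjacent pair."""

    models: pd.DataFrame
    pairs: pd.DataFrame

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# models\n")
            self.models.to_csv(fh, sep="\t", index=False)
            fh.write("# nested comparisons\n")
            self.pairs.to_csv(fh, sep="\t", index=False)


def _model_row(name: str, res: FitResult) -> dict:
    return {
        "model": name,
        "loglik": res.loglik,
        "n_free": res.spec.n_free,
        "chi_square": res.chi_square,
        "df": res.df,
        "p": res.p_value,
        "aic": res.aic,
        "bic": res.bic,
        "rmsea": res.rmsea,
        "srmr": res.srmr,
        "cfi": res.cfi,
    }


def comparison_table(named_fits: list[tuple[str, FitResult]]) -> ComparisonTable:
    """Build a comparison table; adjacent pairs are LR-tested in order."""
    models = pd.DataFrame([_model_row(n, r) for n, r in named_fits])
    pairs = []
    for (name_f, full), (name_n, nested) in zip(named_fits, named_fits[1:]):
        dchi, ddf, p = lr_test(full, nested)
        pairs.append(
            {
                "full": name_f,
                "nested": name_n,
                "delta_chi_square": dchi,
                "delta_df": ddf,
                "p": p,
            }
        )
    return ComparisonTable(models, pd.DataFrame(pairs))


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------


def _free_cells(spec: ModelSpec) -> set[tuple]:
    """Free parameter cells expanded over groups, for nesting checks."""
    cells = set()
    for p in spec.params:
        if not p.free:
            continue
        groups = spec.groups if p.group is None else (p.group,)
        for g in groups:
            cells.add((g, p.matrix, p.loc))
    return cells


def lr_test(full: FitResult, nested: FitResult) -> tuple[float, int, float]:
    """Likelihood-ratio (chi-square difference) test of nested models.

    Returns ``(delta_chi_square, delta_df, p)``.  A negative difference
    (possible under separate ML refits) is floored at zero with a warning.
    """
    if not _free_cells(nested.spec) <= _free_cells(full.spec):
        raise ValueError(
            "models are not nested: the restricted model frees parameters "
            "absent from the full model"
        )
    delta_df = nested.df - full.df
    if delta_df < 0:
        raise ValueError("nested model has fewer df than the full model")
    delta = nested.chi_square - full.chi_square
    if delta < -1e-8:
        warnings.warn(
            f"negative chi-square difference ({delta:.4g}) floored at 0"
        )
    delta = max(delta, 0.0)
    if delta_df == 0:
        return delta, 0, 1.0
    return delta, delta_df, float(chi2.sf(delta, delta_df))


def bh_fdr(p_values, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up procedure.

    Returns ``(q_values, reject)`` where q-values are monotone
    non-decreasing in the sorted order of the p-values.
    """
    p = np.asarray(list(p_values), float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, q, *_ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, reject


# ---------------------------------------------------------------------------
# pruning workflow
# ---------------------------------------------------------------------------


@dataclass
class PruneResult:
    table: ComparisonTable
    fits: dict[str, FitResult]
    edges: pd.DataFrame
    retained: list[str] = field(default_factory=list)
    dropped: list[str] = field(default_factory=list)


def _scope_labels(spec: ModelSpec, path_scope: str) -> list[str]:
    if path_scope == "within_person_cross_lags":
        return spec.labels(matrix="beta", offdiag=True, free=True)
    if path_scope == "between_sibling_paths":
        return spec.labels(matrix="sib", free=True)
    raise ValueError(f"path_scope must be one of {PATH_SCOPES}")


def prune_and_compare(
    spec: ModelSpec,
    data,
    path_scope: str = "within_person_cross_lags",
    correction: str = "fdr",
    alpha: float = 0.05,
    fit_kwargs: dict | None = None,
) -> PruneResult:
    """Full -> pruned -> null workflow over one family of lagged paths.

    All paths in scope are Wald-tested in the fitted full model; the chosen
    correction ('fdr' or 'nominal') is applied jointly over that family; the
    non-significant paths are fixed to zero in a single pass and the pruned
    model refitted; the null model removes every scoped path.  Returns the
    three-model comparison, the fits, and a path table with estimate, SE,
    p, q and retention flags.
    """
    if correction not in ("fdr", "nominal"):
        raise ValueError("correction must be 'fdr' or 'nominal'")
    kwargs = dict(fit_kwargs or {})
    full = fit(spec, data, **kwargs)
    if not full.converged:
        raise RuntimeError("full model did not converge; aborting pruning")
    labels = _scope_labels(spec, path_scope)
    wald = full.wald_table(labels)
    if correction == "fdr":
        q, reject = bh_fdr(wald["p"].to_numpy(), alpha)
    else:
        q = wald["p"].to_numpy()
        reject = q < alpha
    wald = wald.assign(q=q, retained=reject)
    # eq-group deduplication: fixing one member fixes the whole group
    eq_of = {p.label: p.eq for p in spec.params if p.free}
    drop_eqs = {
        eq_of[lab] for lab, keep in zip(wald["label"], wald["retained"]) if not keep
    }
    dropped = [lab for lab in labels if eq_of[lab] in drop_eqs]
    retained = [lab for lab in labels if lab not in dropped]
    pruned_spec = apply_constraints(
        spec, [{"fix": lab, "value": 0.0} for lab in sorted(drop_eqs)]
    )
    null_spec = apply_constraints(
        spec, [{"fix": eq, "value": 0.0} for eq in sorted({eq_of[l] for l in labels})]
    )
    pruned = fit(pruned_spec, data, **kwargs)
    null = fit(null_spec, data, **kwargs)
    named = [("full", full), ("pruned", pruned), ("null", null)]
    table = comparison_table(named)
    logger.info(
        "pruning (%s, %s, alpha=%.3g): retained %d of %d paths",
        path_scope,
        correction,
        alpha,
        len(retained),
        len(labels),
    )
    return PruneResult(
        table=table,
        fits=dict(named),
        edges=wald,
        retained=retained,
        dropped=dropped,
    )


def edge_list(result: PruneResult) -> pd.DataFrame:
    """Network edge list (TSV-ready) from a pruning workflow.

    Levels: 'within-person' (lagged within-person paths),
    'between-sibling' (cross-twin lagged paths), and
    'between-person correlation' (random-intercept correlations).
    """
    full = result.fits["full"]
    spec = full.spec
    ps = full.parameter_set()
    edges = []
    flagged = dict(zip(result.edges["label"], zip(result.edges["q"],
                                                 result.edges["retained"])))
    tl = spec.design.trait_labels
    wl = spec.design.wave_labels
    eq_of = {p.label: p.eq for p in spec.params if p.free}
    for p in spec.params:
        if p.matrix in ("beta", "sib") and p.free:
            w, i, j = p.loc
            level = "within-person" if p.matrix == "beta" else "between-sibling"
            q, kept = flagged.get(p.label, (np.nan, True))
            edges.append(
                {
                    "from": f"{tl[j]}@{wl[w]}",
                    "to": f"{tl[i]}@{wl[w + 1]}",
                    "level": level,
                    "estimate": full.estimates[eq_of[p.label]],
                    "se": full.se[eq_of[p.label]] if full.se else np.nan,
                    "p": float(
                        result.edges.set_index("label")["p"].get(p.label, np.nan)
                    ),
                    "q": q,
                    "retained": bool(kept),
                }
            )
    K = spec.design.n_traits
    sd = np.sqrt(np.clip(np.diag(ps.psi), 1e-300, None))
    for i in range(K):
        for j in range(i):
            edges.append(
                {
                    "from": tl[j],
                    "to": tl[i],
                    "level": "between-person correlation",
                    "estimate": ps.psi[i, j] / (sd[i] * sd[j]),
                    "se": np.nan,
                    "p": np.nan,
                    "q": np.nan,
                    "retained": True,
                }
            )
    return pd.DataFrame(edges)


# ---------------------------------------------------------------------------
# sex multi-group test
# ---------------------------------------------------------------------------


def sex_multigroup_test(
    spec: ModelSpec,
    data,
    groups: tuple[str, str] = ("male", "female"),
    fit_kwargs: dict | None = None,
) -> tuple[ComparisonTable, dict[str, FitResult]]:
    """Test whether lagged regressions differ between the sexes.

    Builds two multi-group variants of a single-group RI-CLPM spec: one
    with every parameter split by sex, and a nested one in which the lag
    matrices are equated across the sexes while all other parameters remain
    sex-specific.  Returns the LR comparison (split vs equated) and both
    fits.  ``data`` must be groupable by sex (a TwinDataset with a sex
    column, or a mapping with the group labels).
    """
    if len(spec.groups) != 1:
        raise ValueError("sex_multigroup_test expects a single-group spec")
    kwargs = dict(fit_kwargs or {})
    regrouped = ModelSpec(
        spec.design.with_groups(groups), spec.kind, [p for p in spec.copy().params]
    )
    free = [p.label for p in regrouped.params if p.free]
    lag_labels = set(regrouped.labels(matrix="beta", free=True))
    split_all = apply_constraints(
        regrouped, [{"split_by_group": lab} for lab in free]
    )
    split_non_lag = apply_constraints(
        regrouped,
        [{"split_by_group": lab} for lab in free if lab not in lag_labels],
    )
    split_fit = fit(split_all, data, **kwargs)
    equated_fit = fit(split_non_lag, data, **kwargs)
    table = comparison_table(
        [("regressions split by sex", split_fit),
         ("regressions equated", equated_fit)]
    )
    return table, {"split": split_fit, "equated": equated_fit}
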