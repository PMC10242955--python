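"""Panel data containers, preprocessing and plain-text I/O.

The wide data layout has one row per family and columns
``family_id, zygosity, sex_1, sex_2, age_<wave>_<sib>, <trait>_<wave>_<sib>``
with missing values as empty CSV cells.  Preprocessing mirrors the standard
cohort pipeline for parent-rated problem-behaviour scores: restrict each
wave to a non-overlapping age bin, residualize scores on sex and age within
each wave, z-standardize the residuals, and (for single-person analyses)
select one random sibling per pair.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .model_builder import DesignError, PanelDesign, ValidationError

__all__ = [
    "TwinDataset",
    "AgeBin",
    "AgeBinRule",
    "score_columns",
    "read_csv",
    "bin_by_age",
    "residualize_standardize",
    "select_one_per_pair",
    "write_moments",
    "read_moments",
]


def score_columns(design: PanelDesign) -> list[str]:
    """Canonical score column order: sibling-major, wave, then trait."""
    return [
        f"{trait}_{wave}_{s + 1}"
        for s in range(design.n_siblings)
        for wave in design.wave_labels
        for trait in design.trait_labels
    ]


def age_columns(design: PanelDesign) -> list[str]:
    return [
        f"age_{wave}_{s + 1}"
        for s in range(design.n_siblings)
        for wave in design.wave_labels
    ]


@dataclass
class TwinDataset:
    """Wide panel of families with zygosity, optional sex/age, and scores."""

    df: pd.DataFrame
    design: PanelDesign

    def __post_init__(self) -> None:
        missing = [c for c in score_columns(self.design) if c not in self.df.columns]
        if missing:
            raise DesignError(f"dataset lacks score columns: {missing[:5]} ...")
        if self.design.n_siblings == 2 and "zygosity" not in self.df.columns:
            raise DesignError("two-sibling datasets require a zygosity column")

    @property
    def n_families(self) -> int:
        return len(self.df)

    def scores(self) -> np.ndarray:
        """(n, d) score matrix in canonical column order (NaN = missing)."""
        return self.df[score_columns(self.design)].to_numpy(float)

    def group_arrays(self, by: str | None = None) -> dict[str, np.ndarray]:
        """Per-group score matrices keyed by zygosity/sex/'all'.

        ``by='sex'`` groups single-person panels on the ``sex_1`` column
        (values are used as group labels, e.g. 'male'/'female').
        """
        X = self.scores()
        if by is None:
            if self.design.n_siblings == 2:
                by = "zygosity"
            else:
                return {"all": X}
        col = "sex_1" if by == "sex" else by
        if col not in self.df.columns:
            raise DesignError(f"dataset lacks a {col!r} column")
        keys = self.df[col].astype(str).to_numpy()
        return {g: X[keys == g] for g in pd.unique(keys)}

    def write_csv(self, path) -> None:
        """Round-trip-safe wide CSV (missing cells written empty).

        Floats are written with 17 significant digits so a write/read cycle
        reproduces every score bit-exactly.
        """
        self.df.to_csv(path, index=False, na_rep="", float_format="%.17g")

    def copy_with(self, df: pd.DataFrame) -> "TwinDataset":
        return TwinDataset(df.reset_index(drop=True), self.design)


def read_csv(path, design: PanelDesign) -> TwinDataset:
    df = pd.read_csv(
        path,
        dtype={"family_id": str, "zygosity": str},
        float_precision="round_trip",
    )
    return TwinDataset(df, design)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AgeBin:
    wave: str
    lo: float
    hi: float


class AgeBinRule:
    """Ordered, non-overlapping age windows, one per wave."""

    def __init__(self, bins: list[AgeBin]):
        self.bins = list(bins)
        for a, b in zip(self.bins, self.bins[1:]):
            if a.hi > b.lo:
                raise ValidationError(
                    f"age bins overlap: wave {a.wave} [{a.lo}, {a.hi}] vs "
                    f"wave {b.wave} [{b.lo}, {b.hi}]"
                )
        for b in self.bins:
            if b.lo >= b.hi:
                raise ValidationError(f"empty age bin for wave {b.wave}")

    @classmethod
    def from_dict(cls, d: dict[str, tuple[float, float]]) -> "AgeBinRule":
        return cls([AgeBin(w, lo, hi) for w, (lo, hi) in d.items()])


def bin_by_age(
    dataset: TwinDataset, rules: AgeBinRule
) -> tuple[TwinDataset, dict[str, int]]:
    """Blank out scores whose age falls outside the wave's bin.

    Returns the filtered dataset and per-wave exclusion counts (number of
    score cells set missing because the sibling's age at that wave was out
    of range or missing while a score was present).
    """
    design = dataset.design
    df = dataset.df.copy()
    exclusions = {b.wave: 0 for b in rules.bins}
    for b in rules.bins:
        if b.wave not in design.wave_labels:
            raise ValidationError(f"no wave labelled {b.wave!r} in the design")
        for s in range(design.n_siblings):
            age_col = f"age_{b.wave}_{s + 1}"
            if age_col not in df.columns:
                raise ValidationError(f"dataset lacks {age_col!r}")
            age = df[age_col].to_numpy(float)
            out = ~((age >= b.lo) & (age <= b.hi))
            for trait in design.trait_labels:
                col = f"{trait}_{b.wave}_{s + 1}"
                present = df[col].notna().to_numpy()
                n_drop = int((present & out).sum())
                exclusions[b.wave] += n_drop
                if n_drop:
                    df.loc[present & out, col] = np.nan
    return dataset.copy_with(df), exclusions


def residualize_standardize(dataset: TwinDataset) -> TwinDataset:
    """Z-standardized OLS residuals of each score on sex and age, per wave.

    Regression is cross-sectional (separately per wave/trait) on an
    intercept, sex and age, pooling both siblings; residuals are scaled to
    mean 0 and variance 1 (denominator n-1).  Missing scores stay missing.
    """
    design = dataset.design
    df = dataset.df.copy()
    for wave in design.wave_labels:
        for trait in design.trait_labels:
            y_parts, x_parts, where = [], [], []
            for s in range(design.n_siblings):
                col = f"{trait}_{wave}_{s + 1}"
                y = df[col].to_numpy(float)
                sex = df.get(f"sex_{s + 1}")
                age = df.get(f"age_{wave}_{s + 1}")
                n = len(df)
                sex = np.zeros(n) if sex is None else sex.to_numpy(float)
                age = np.zeros(n) if age is None else age.to_numpy(float)
                y_parts.append(y)
                x_parts.append(np.column_stack([np.ones(n), sex, age]))
                where.append((col, np.arange(n)))
            y_all = np.concatenate(y_parts)
            X_all = np.vstack(x_parts)
            obs = np.isfinite(y_all) & np.isfinite(X_all).all(axis=1)
            if obs.sum() < 3:
                raise ValidationError(
                    f"fewer than 3 non-missing cases for {trait} at wave {wave}"
                )
            if np.ptp(y_all[obs]) == 0:
                raise ValidationError(
                    f"constant score column for {trait} at wave {wave}"
                )
            # drop covariate columns without variation (e.g. absent sex/age)
            keep = [0] + [
                j for j in (1, 2) if np.ptp(X_all[obs, j]) > 0
            ]
            coef, *_ = np.linalg.lstsq(X_all[np.ix_(obs, keep)], y_all[obs], rcond=None)
            resid = np.full(y_all.shape, np.nan)
            resid[obs] = y_all[obs] - X_all[np.ix_(obs, keep)] @ coef
            z = (resid - np.nanmean(resid)) / np.nanstd(resid, ddof=1)
            n = len(df)
            for s, (col, rows) in enumerate(where):
                df[col] = z[s * n : (s + 1) * n]
    return dataset.copy_with(df)


def select_one_per_pair(dataset: TwinDataset, seed: int) -> TwinDataset:
    """Uniformly select one sibling per family, yielding a 1-sibling panel."""
    design = dataset.design
    if design.n_siblings != 2:
        raise DesignError("select_one_per_pair requires a two-sibling dataset")
    rng = np.random.default_rng(seed)
    pick = rng.integers(0, 2, size=len(dataset.df))  # 0 -> sibling 1
    single = replace(design, n_siblings=1, groups=("all",))
    df = dataset.df.copy()
    out = pd.DataFrame({"family_id": df.get("family_id", pd.RangeIndex(len(df)))})
    out["selected_sibling"] = pick + 1
    if "zygosity" in df.columns:
        out["zygosity"] = df["zygosity"].to_numpy()
    for target, sources in [("sex_1", ("sex_1", "sex_2"))]:
        if all(c in df.columns for c in sources):
            vals = np.where(pick == 0, df[sources[0]], df[sources[1]])
            out[target] = vals
    for wave in design.wave_labels:
        srcs = (f"age_{wave}_1", f"age_{wave}_2")
        if all(c in df.columns for c in srcs):
            out[f"age_{wave}_1"] = np.where(pick == 0, df[srcs[0]], df[srcs[1]])
    for wave in design.wave_labels:
        for trait in design.trait_labels:
            srcs = (f"{trait}_{wave}_1", f"{trait}_{wave}_2")
            out[f"{trait}_{wave}_1"] = np.where(pick == 0, df[srcs[0]], df[srcs[1]])
    return TwinDataset(out, single)


# ---------------------------------------------------------------------------
# moment files
# ---------------------------------------------------------------------------


def write_moments(
    path,
    moments: dict[str, tuple[np.ndarray, np.ndarray, int]],
    variables: list[str],
) -> None:
    """Write per-group labelled mean vectors and covariance matrices.

    Plain-text format, one block per group::

        group: MZ
        n: 500
        variables: <tab-separated names>
        mean: <tab-separated values>
        cov:
        <d rows of tab-separated values>
    """
    with open(path, "w") as fh:
        for g, (mean, cov, n) in moments.items():
            fh.write(f"group: {g}\n")
            fh.write(f"n: {int(n)}\n")
            fh.write("variables: " + "\t".join(variables) + "\n")
            fh.write("mean: " + "\t".join(f"{v:.17g}" for v in mean) + "\n")
            fh.write("cov:\n")
            for row in np.asarray(cov):
                fh.write("\t".join(f"{v:.17g}" for v in row) + "\n")
            fh.write("\n")


def read_moments(path) -> tuple[dict[str, tuple[np.ndarray, np.ndarray, int]], list[str]]:
    """Read the plain-text moment format written by :func:`write_moments`."""
    moments: dict[str, tuple[np.ndarray, np.ndarray, int]] = {}
    variables: list[str] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    i = 0
    while i < len(lines):
        if not lines[i].startswith("group:"):
            i += 1
            continue
        g = lines[i].split(":", 1)[1].strip()
        n = int(lines[i + 1].split(":", 1)[1])
        variables = lines[i + 2].split(":", 1)[1].strip().split("\t")
        mean = np.array(
            [float(v) for v in lines[i + 3].split(":", 1)[1].strip().split("\t")]
        )
        d = len(mean)
        cov = np.array(
            [[float(v) for v in lines[i + 5 + r].split("\t")] for r in range(d)]
        )
        moments[g] = (mean, cov, n)
        i += 5 + d
    if not moments:
        raise ValidationError(f"no moment blocks found in {path}")
    return moments, variables
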