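"""Diversity indices, constrained correspondence analysis, envfit-style
environmental association, and fermentation-table summaries.

CCA ordinates a chi-square-standardized abundance matrix constrained to
linear combinations of environmental variables (ter Braak).  envfit follows
the vegan convention: the squared multiple correlation (R²) of an
environmental vector regressed on the first two ordination axes, with a
permutation p-value using the add-one estimator
``p = (1 + #{R²_perm >= R²_obs}) / (1 + n_perm)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skbio.stats.ordination import cca as _skbio_cca

__all__ = [
    "shannon",
    "simpson",
    "cca",
    "OrdinationResult",
    "envfit",
    "envfit_all",
    "summarize_fermentation",
]


def _proportions(abundances) -> np.ndarray:
    a = np.asarray(abundances, dtype=float)
    if (a < 0).any():
        raise ValueError("abundances must be non-negative")
    total = a.sum()
    if total <= 0:
        raise ValueError("all-zero abundance vector")
    return a / total


def shannon(abundances) -> float:
    """Shannon diversity H = -sum p_i ln p_i (nats); zero terms contribute 0."""
    return float(stats.entropy(_proportions(abundances)))


def simpson(abundances, variant: str = "gini") -> float:
    """Simpson diversity.

    ``variant="gini"`` (default) returns the Gini–Simpson index
    1 - sum p_i^2; ``variant="lambda"`` returns the raw concentration
    sum p_i^2.
    """
    p = _proportions(abundances)
    lam = float((p**2).sum())
    if variant == "gini":
        return 1.0 - lam
    if variant == "lambda":
        return lam
    raise ValueError(f"unknown Simpson variant '{variant}'")


@dataclass
class OrdinationResult:
    """Constrained-ordination output.

    ``site_scores`` are weighted-average (WA) sample scores,
    ``constraint_scores`` the linear-combination (LC) scores; eigenvalues
    cover the constrained axes only.
    """

    site_scores: pd.DataFrame
    constraint_scores: pd.DataFrame
    species_scores: pd.DataFrame
    eigenvalues: pd.Series
    total_inertia: float
    constrained_inertia: float


def _check_collinearity(X: pd.DataFrame) -> None:
    Xc = X.to_numpy(float) - X.to_numpy(float).mean(axis=0)
    rank = 0
    for j in range(Xc.shape[1]):
        new_rank = np.linalg.matrix_rank(Xc[:, : j + 1])
        if new_rank == rank:
            raise ValueError(
                f"constraint '{X.columns[j]}' is collinear with preceding columns"
            )
        rank = new_rank


def total_inertia(abundance: pd.DataFrame) -> float:
    """Total chi-square inertia of a samples × species abundance table."""
    P = abundance.to_numpy(float)
    P = P / P.sum()
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    E = np.outer(r, c)
    with np.errstate(invalid="ignore", divide="ignore"):
        cells = np.where(E > 0, (P - E) ** 2 / E, 0.0)
    return float(cells.sum())


def cca(abundance: pd.DataFrame, constraints: pd.DataFrame) -> OrdinationResult:
    """Constrained correspondence analysis (samples × species vs samples ×
    environmental variables).

    Requires >= 3 samples, no all-zero row or column, and fewer constraint
    variables than samples.  Axes are ordered by eigenvalue; signs are
    arbitrary.  Tables with no chi-square structure (all rows proportional)
    return an empty result with zero inertia.
    """
    if len(abundance) < 3:
        raise ValueError("need at least 3 samples")
    if not abundance.index.equals(constraints.index):
        constraints = constraints.loc[abundance.index]
    Y = abundance.to_numpy(float)
    if (Y < 0).any():
        raise ValueError("abundance values must be non-negative")
    if (Y.sum(axis=1) == 0).any():
        bad = abundance.index[Y.sum(axis=1) == 0].tolist()
        raise ValueError(f"all-zero sample row(s): {bad}")
    if (Y.sum(axis=0) == 0).any():
        bad = abundance.columns[Y.sum(axis=0) == 0].tolist()
        raise ValueError(f"all-zero species column(s): {bad}")
    if constraints.shape[1] >= len(abundance):
        raise ValueError("number of constraint variables must be < number of samples")
    _check_collinearity(constraints)

    inertia = total_inertia(abundance)
    n_axes = min(constraints.shape[1], abundance.shape[1] - 1)
    if inertia < 1e-12 or n_axes == 0:
        empty = pd.DataFrame(index=abundance.index)
        return OrdinationResult(
            empty, empty.copy(), pd.DataFrame(index=abundance.columns),
            pd.Series(dtype=float), inertia, 0.0,
        )

    res = _skbio_cca(abundance.astype(float), constraints.astype(float))
    axes = [f"CCA{i + 1}" for i in range(n_axes)]
    eig = res.eigvals[axes]
    return OrdinationResult(
        site_scores=res.samples[axes],
        constraint_scores=res.sample_constraints[axes],
        species_scores=res.features[axes],
        eigenvalues=eig,
        total_inertia=inertia,
        constrained_inertia=float(eig.sum()),
    )


def envfit(
    site_scores: pd.DataFrame,
    env: pd.Series,
    n_perm: int = 999,
    seed: int = 0,
    n_axes: int = 2,
) -> tuple[float, float]:
    """Fit an environmental vector onto ordination axes.

    R² is the coefficient of determination of the least-squares regression
    of ``env`` on the first ``n_axes`` site-score axes; the permutation
    p-value uses the add-one estimator and is deterministic under ``seed``.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    scores = site_scores.iloc[:, :n_axes]
    if not env.index.equals(scores.index):
        env = env.loc[scores.index]
    y = env.to_numpy(float)
    if np.ptp(y) == 0:
        raise ValueError(f"constant environmental variable '{env.name}': R² undefined")
    X = np.column_stack([np.ones(len(y)), scores.to_numpy(float)])
    hat = X @ np.linalg.pinv(X)

    def r2(v: np.ndarray) -> float:
        resid = v - hat @ v
        sst = ((v - v.mean()) ** 2).sum()
        return 1.0 - resid @ resid / sst

    observed = r2(y)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        if r2(rng.permutation(y)) >= observed - 1e-12:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return float(observed), float(p)


def envfit_all(
    site_scores: pd.DataFrame,
    env_table: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
    n_axes: int = 2,
) -> pd.DataFrame:
    """envfit every (numeric, non-constant) environment column; BH across
    variables."""
    from .abundance import bh_fdr

    rows = []
    rng = np.random.default_rng(seed)
    for col in env_table.columns:
        series = env_table[col]
        if not pd.api.types.is_numeric_dtype(series):
            continue
        sub_seed = int(rng.integers(0, 2**31 - 1))
        try:
            r2, p = envfit(site_scores, series, n_perm=n_perm, seed=sub_seed,
                           n_axes=n_axes)
        except ValueError:
            warnings.warn(f"skipping constant variable '{col}'")
            continue
        rows.append({"variable": col, "R2": r2, "p": p})
    out = pd.DataFrame(rows)
    if not out.empty:
        out["q"] = bh_fdr(out["p"].to_numpy())
    return out


def summarize_fermentation(env_table: pd.DataFrame) -> pd.DataFrame:
    """Group mean ± SEM of fermentation variables.

    Total SCFA per sample = acetate + propionate + butyrate; the L/D
    lactate ratio is computed per sample and then averaged (mean of
    ratios).  Samples with D-lactate = 0 have an undefined ratio and are
    excluded from the ratio summary with a warning.
    """
    df = env_table.copy()
    counts = df.groupby("group").size()
    small = counts[counts < 2]
    if not small.empty:
        raise ValueError(f"group(s) with <2 samples: {small.index.tolist()}")
    df["total_scfa_mM"] = (
        df["acetate_mM"] + df["propionate_mM"] + df["butyrate_mM"]
    )
    zero_d = df["d_lactate_mM"] == 0
    if zero_d.any():
        warnings.warn(
            f"D-lactate = 0 in sample(s) {df.index[zero_d].tolist()}; "
            "L/D ratio excluded there"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        df["ld_ratio"] = np.where(
            zero_d, np.nan, df["l_lactate_mM"] / df["d_lactate_mM"]
        )
    value_cols = [c for c in df.columns if c != "group"
                  and pd.api.types.is_numeric_dtype(df[c])]
    mean = df.groupby("group")[value_cols].mean()
    sem = df.groupby("group")[value_cols].sem()
    out = pd.concat({"mean": mean, "sem": sem}, axis=1)
    out.columns = [f"{stat}_{var}" for stat, var in out.columns]
    return out
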