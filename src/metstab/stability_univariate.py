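"""Univariate stability statistics for genotype × environment mean tables.

Four classical families are implemented on the cell-means basis:

* Eberhart–Russell joint regression: each genotype's environment means
  are regressed on the environment index I_j (environment mean minus
  grand mean); the slope b_i measures responsiveness and the deviation
  mean square S²d_i measures nonlinearity.  The classical estimator
  subtracts the replicate error contribution MSE/r from the deviation MS;
  the raw deviation MS is available by flag.
* Perkins–Jinks: the same regression applied to the interaction
  deviations, giving B_i = b_i − 1 and the (raw) deviation MS DJ_i.
* Wricke's ecovalence W_i: the genotype's summed squared interaction
  residuals — its contribution to the interaction sum of squares.
* Francis–Kannenberg: standard deviation and coefficient of variation of
  the genotype's environment means.

A genotype is "stable" in the joint-regression sense when b_i ≈ 1 and
S²d_i ≈ 0; b_i > 1 indicates specific adaptation to favorable (high
index) environments, b_i < 1 to unfavorable ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .met_core import TwoWayTable

__all__ = [
    "EnvironmentIndex",
    "environment_index",
    "er_regression",
    "pj_regression",
    "wricke_ecovalence",
    "francis_kannenberg",
    "classify_adaptation",
    "stability_table",
]


@dataclass(frozen=True)
class EnvironmentIndex:
    """Environment index I_j = X_.j − X.. (sums to zero over environments)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if abs(self.values.sum()) > 1e-10 * max(1.0, np.abs(self.values).max()):
            raise ValueError("environment index must sum to zero")


def environment_index(table: TwoWayTable) -> EnvironmentIndex:
    """Index each environment by its mean deviation from the grand mean."""
    return EnvironmentIndex(values=table.environment_means - table.grand_mean)


def er_regression(
    table: TwoWayTable,
    index: EnvironmentIndex | None = None,
    error_correction: bool = True,
) -> pd.DataFrame:
    """Eberhart–Russell slopes and deviation mean squares, per genotype.

    Returns a frame indexed by genotype with columns ``bi``, ``s2di``,
    ``t_bi`` / ``p_bi`` (H0: b_i = 1) and ``f_s2di`` / ``p_s2di``
    (H0: S²d_i = 0, available when the table carries a pooled error).

    With ``error_correction`` the deviation MS is the classical estimator
    Σδ²/(e−2) − MSE/r; otherwise the raw deviation MS Σδ²/(e−2).
    """
    if index is None:
        index = environment_index(table)
    e = table.n_environments
    if e < 3:
        raise ValueError("joint regression needs at least 3 environments (e-2 df)")
    I = index.values
    ss_I = float((I ** 2).sum())
    if ss_I == 0.0:
        raise ValueError("environment index is identically zero: slope undefined")

    centered = table.means - table.genotype_means[:, None]
    bi = centered @ I / ss_I
    resid = centered - np.outer(bi, I)
    dev_ms_raw = (resid ** 2).sum(axis=1) / (e - 2)
    correction = table.pooled_error_ms / table.replicates if table.replicates else 0.0
    s2di = dev_ms_raw - correction if error_correction else dev_ms_raw

    # t for H0: slope = 1 using each genotype's own deviation variance
    se_bi = np.sqrt(np.maximum(dev_ms_raw, 0.0) / ss_I)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_bi = np.where(se_bi > 0, (bi - 1.0) / se_bi, np.inf * np.sign(bi - 1.0))
    p_bi = 2.0 * stats.t.sf(np.abs(t_bi), e - 2)

    out = pd.DataFrame(
        {"bi": bi, "s2di": s2di, "t_bi": t_bi, "p_bi": p_bi},
        index=pd.Index(table.genotypes, name="genotype"),
    )
    if table.replicates > 1 and table.pooled_error_ms > 0:
        f = dev_ms_raw / (table.pooled_error_ms / table.replicates)
        df_err = table.n_genotypes * e * (table.replicates - 1)
        out["f_s2di"] = f
        out["p_s2di"] = stats.f.sf(f, e - 2, df_err)
    return out


def pj_regression(
    table: TwoWayTable, index: EnvironmentIndex | None = None
) -> pd.DataFrame:
    """Perkins–Jinks slope deviations B_i = b_i − 1 and deviation MS DJ_i.

    B_i is the regression of the interaction residual
    (x_ij − X_i. − X_.j + X..) on I_j; its residuals coincide with the
    Eberhart–Russell residuals, so DJ_i equals the raw ER deviation MS.
    """
    if index is None:
        index = environment_index(table)
    e = table.n_environments
    if e < 3:
        raise ValueError("joint regression needs at least 3 environments (e-2 df)")
    I = index.values
    ss_I = float((I ** 2).sum())
    if ss_I == 0.0:
        raise ValueError("environment index is identically zero: slope undefined")
    z = table.interaction_residuals()
    Bi = z @ I / ss_I
    resid = z - np.outer(Bi, I)
    dji = (resid ** 2).sum(axis=1) / (e - 2)
    return pd.DataFrame(
        {"Bi": Bi, "dji": dji},
        index=pd.Index(table.genotypes, name="genotype"),
    )


def wricke_ecovalence(table: TwoWayTable) -> pd.Series:
    """W_i = Σ_j (x_ij − X_i. − X_.j + X..)², each genotype's share of SS_GE."""
    z = table.interaction_residuals()
    return pd.Series(
        (z ** 2).sum(axis=1), index=pd.Index(table.genotypes, name="genotype"),
        name="wi",
    )


def francis_kannenberg(table: TwoWayTable) -> pd.DataFrame:
    """Per-genotype sd and CV% of the environment means."""
    if table.n_environments < 2:
        raise ValueError("need at least 2 environments for a standard deviation")
    sd = table.means.std(axis=1, ddof=1)
    means = table.genotype_means
    if np.any(means == 0):
        raise ZeroDivisionError("genotype mean of 0: CV undefined")
    cv = 100.0 * sd / np.abs(means)
    return pd.DataFrame(
        {"sd": sd, "cv": cv}, index=pd.Index(table.genotypes, name="genotype")
    )


def classify_adaptation(
    bi: pd.Series, genotype_means: pd.Series, grand_mean: float, tol: float = 0.05
) -> pd.DataFrame:
    """Verbal adaptation classes from the joint-regression slope.

    Slopes above 1 + tol mark adaptation to favorable (high-index)
    environments, below 1 − tol to unfavorable ones, else average
    responsiveness; crossed with above/below grand-mean performance.
    """
    slope_class = pd.Series(
        np.where(bi > 1 + tol, "favorable", np.where(bi < 1 - tol, "unfavorable", "average")),
        index=bi.index,
        name="adaptation_class",
    )
    performance = pd.Series(
        np.where(genotype_means > grand_mean, "above-average", "below-average"),
        index=bi.index,
        name="performance_class",
    )
    return pd.concat([slope_class, performance], axis=1)


def stability_table(
    table: TwoWayTable, error_correction: bool = True, tol: float = 0.05
) -> pd.DataFrame:
    """All univariate stability measures in one frame (report layout).

    Columns: mean, sd, cv, bi, s2di, Bi, dji, wi, adaptation_class,
    performance_class — one row per genotype.
    """
    index = environment_index(table)
    fk = francis_kannenberg(table)
    er = er_regression(table, index, error_correction=error_correction)
    pj = pj_regression(table, index)
    wi = wricke_ecovalence(table)
    means = pd.Series(
        table.genotype_means, index=pd.Index(table.genotypes, name="genotype"),
        name="mean",
    )
    classes = classify_adaptation(er["bi"], means, table.grand_mean, tol=tol)
    return pd.concat(
        [means, fk, er[["bi", "s2di"]], pj, wi, classes], axis=1
    )
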