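"""AMMI: additive main effects with a multiplicative interaction term.

The model for a genotype × environment mean table is

    x_ge = mu + alpha_g + beta_e + sum_n lambda_n gamma_gn delta_en + rho_ge

where the main effects are the usual row/column deviations and the
interaction is decomposed by SVD of the double-centered matrix
z_ge = x_ge − X_g. − X_.e + X.. .  The lambda_n are the singular values
in decreasing order and the score columns gamma_.n, delta_.n are
orthonormal.  By the Eckart–Young identity sum lambda_n² equals the
interaction sum of squares, so each axis's share of SS_GE is
lambda_n²/SS_GE.

Interaction principal component axis (IPCA) n carries Gollob degrees of
freedom g + e − 1 − 2n, which sum to (g−1)(e−1) over the full rank.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .met_core import TwoWayTable
from .pooled_anova import AnovaRow, AnovaTable, env_collapsed_anova, _f_test

__all__ = [
    "AMMIModel",
    "fit_ammi",
    "gollob_df",
    "ammi_anova",
    "ammi1_coords",
    "ammi2_coords",
]


def gollob_df(g: int, e: int, n: int) -> int:
    """Gollob degrees of freedom g + e − 1 − 2n for the n-th IPCA (n ≥ 1)."""
    if n < 1:
        raise ValueError("component index n starts at 1")
    return g + e - 1 - 2 * n


@dataclass
class AMMIModel:
    """Fitted AMMI decomposition of a two-way table.

    ``genotype_scores`` (g × n) and ``environment_scores`` (e × n) hold
    the orthonormal singular vectors; multiply by ``singular_values`` to
    reconstruct the interaction.  ``scaling`` is the exponent s used when
    producing biplot coordinates (lambda^s to genotypes, lambda^(1−s) to
    environments); s = 0.5 is the symmetric convention.
    """

    trait: str
    genotypes: list[str]
    environments: list[str]
    grand_mean: float
    genotype_effects: np.ndarray
    environment_effects: np.ndarray
    singular_values: np.ndarray
    genotype_scores: np.ndarray
    environment_scores: np.ndarray
    basis: str = "means"
    scaling: float = 0.5

    @property
    def rank(self) -> int:
        return len(self.singular_values)

    @property
    def n_genotypes(self) -> int:
        return len(self.genotypes)

    @property
    def n_environments(self) -> int:
        return len(self.environments)

    def interaction(self, n_axes: int | None = None) -> np.ndarray:
        """Rank-``n_axes`` reconstruction of the interaction matrix."""
        n = self.rank if n_axes is None else min(n_axes, self.rank)
        u = self.genotype_scores[:, :n]
        v = self.environment_scores[:, :n]
        return (u * self.singular_values[:n]) @ v.T

    def fitted(self, n_axes: int | None = None) -> np.ndarray:
        """Reconstructed cell means mu + alpha + beta + truncated interaction."""
        return (
            self.grand_mean
            + self.genotype_effects[:, None]
            + self.environment_effects[None, :]
            + self.interaction(n_axes)
        )

    def scaled_scores(self, side: str, n_axes: int = 2) -> np.ndarray:
        """Biplot coordinates: lambda^s × genotype scores, lambda^(1−s) × env."""
        n = min(n_axes, self.rank)
        lam = self.singular_values[:n]
        if side == "genotype":
            return self.genotype_scores[:, :n] * lam ** self.scaling
        if side == "environment":
            return self.environment_scores[:, :n] * lam ** (1.0 - self.scaling)
        raise ValueError("side must be 'genotype' or 'environment'")


def _svd_with_sign_convention(z: np.ndarray):
    """SVD with each environment-score column flipped so its largest-magnitude
    element is positive (deterministic orientation across platforms)."""
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    v = vt.T
    for k in range(v.shape[1]):
        j = int(np.argmax(np.abs(v[:, k])))
        if v[j, k] < 0:
            v[:, k] = -v[:, k]
            u[:, k] = -u[:, k]
    return u, s, v


def fit_ammi(table: TwoWayTable, basis: str = "means", scaling: float = 0.5) -> AMMIModel:
    """Fit the AMMI decomposition to a two-way table.

    ``basis`` tags the scale used by :func:`ammi_anova` (plot multiplies
    means-based SS by the replicate count); the decomposition itself is
    always of the cell-mean interaction matrix.  An additive table is not
    an error: all singular values come back 0.
    """
    g, e = table.n_genotypes, table.n_environments
    if g < 3 or e < 3:
        raise ValueError("AMMI needs at least 3 genotypes and 3 environments")
    if not 0.0 <= scaling <= 1.0:
        raise ValueError("scaling exponent must lie in [0, 1]")
    z = table.interaction_residuals()
    u, s, v = _svd_with_sign_convention(z)
    n = min(g - 1, e - 1)
    return AMMIModel(
        trait=table.trait,
        genotypes=list(table.genotypes),
        environments=list(table.environments),
        grand_mean=table.grand_mean,
        genotype_effects=table.genotype_means - table.grand_mean,
        environment_effects=table.environment_means - table.grand_mean,
        singular_values=s[:n],
        genotype_scores=u[:, :n],
        environment_scores=v[:, :n],
        basis=basis,
        scaling=scaling,
    )


def ammi_anova(
    model: AMMIModel, table: TwoWayTable, n_axes: int = 2
) -> AnovaTable:
    """G / E / G×E ANOVA with the interaction split into IPCA axes.

    The first ``n_axes`` axes get Gollob df and, on the plot basis, an F
    test against the pooled error; the remaining axes are pooled into a
    single residual row.  Each axis's percentage explained is relative to
    SS_GE.
    """
    if n_axes > model.rank:
        raise ValueError(f"n_axes={n_axes} exceeds available rank {model.rank}")
    base = env_collapsed_anova(table, basis=model.basis)
    g, e, r = model.n_genotypes, model.n_environments, table.replicates
    scale = r if model.basis == "plot" else 1
    ss_ge = base["G x E"].ss

    err_ms = table.pooled_error_ms if model.basis == "plot" else 0.0
    df_err = g * e * (r - 1) if model.basis == "plot" else 0

    rows = list(base.rows)
    insert_at = base.sources.index("G x E") + 1
    used_ss = 0.0
    used_df = 0
    for n in range(1, n_axes + 1):
        ss_n = scale * float(model.singular_values[n - 1] ** 2)
        df_n = gollob_df(g, e, n)
        row = AnovaRow(f"IPCA{n}", df_n, ss_n)
        row.pct_explained = 100.0 * ss_n / ss_ge if ss_ge > 0 else None
        if df_err > 0:
            row.f, row.p = _f_test(row.ms, err_ms, df_n, df_err)
        rows.insert(insert_at, row)
        insert_at += 1
        used_ss += ss_n
        used_df += df_n
    df_res = (g - 1) * (e - 1) - used_df
    if df_res > 0:
        res = AnovaRow("IPCA residual", df_res, max(ss_ge - used_ss, 0.0))
        res.pct_explained = 100.0 * res.ss / ss_ge if ss_ge > 0 else None
        if df_err > 0:
            res.f, res.p = _f_test(res.ms, err_ms, df_res, df_err)
        rows.insert(insert_at, res)
    return AnovaTable(rows=rows, basis=model.basis)


def ammi1_coords(model: AMMIModel) -> pd.DataFrame:
    """AMMI1 biplot coordinates: main-effect abscissa vs scaled IPCA1 ordinate.

    Genotypes sit at mu + alpha_g, environments at mu + beta_e on the
    abscissa; the ordinate is the symmetrically scaled first interaction
    score, so points near the zero line interact little.
    """
    lam = model.singular_values
    g_ord = model.scaled_scores("genotype", 1)[:, 0] if model.rank else np.zeros(model.n_genotypes)
    e_ord = model.scaled_scores("environment", 1)[:, 0] if model.rank else np.zeros(model.n_environments)
    recs = [
        {"entity": name, "kind": "genotype", "mean": model.grand_mean + a, "ipca1": s}
        for name, a, s in zip(model.genotypes, model.genotype_effects, g_ord)
    ] + [
        {"entity": name, "kind": "environment", "mean": model.grand_mean + b, "ipca1": s}
        for name, b, s in zip(model.environments, model.environment_effects, e_ord)
    ]
    return pd.DataFrame(recs)


def ammi2_coords(model: AMMIModel) -> pd.DataFrame:
    """AMMI2 biplot coordinates with distance-from-origin stability ranks.

    Requires rank ≥ 2.  A genotype's Euclidean distance from the origin in
    the (IPCA1, IPCA2) plane is the AMMI2 stability criterion: smaller is
    more stable.  Ranks are ascending in distance (1 = most stable) and
    invariant to the SVD sign convention.
    """
    if model.rank < 2:
        raise ValueError("AMMI2 needs at least two interaction components")
    gs = model.scaled_scores("genotype", 2)
    es = model.scaled_scores("environment", 2)
    recs = []
    for name, (x, y) in zip(model.genotypes, gs):
        recs.append(
            {"entity": name, "kind": "genotype", "ipca1": x, "ipca2": y,
             "distance": float(np.hypot(x, y))}
        )
    for name, (x, y) in zip(model.environments, es):
        recs.append(
            {"entity": name, "kind": "environment", "ipca1": x, "ipca2": y,
             "distance": float(np.hypot(x, y))}
        )
    df = pd.DataFrame(recs)
    is_g = df["kind"] == "genotype"
    df.loc[is_g, "stability_rank"] = (
        df.loc[is_g, "distance"].rank(method="first").astype(int)
    )
    return df
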