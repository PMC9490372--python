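"""GGE biplot engine: genotype main effect + genotype × environment signal.

Centering each environment's column of the cell-mean table removes the
environment main effect and leaves G + GE, the part of the variation
relevant to genotype evaluation.  The SVD of this matrix, truncated to
rank 2, yields the biplot; singular-value partitioning (SVP) decides how
the singular values are allocated between genotype and environment
markers:

* genotype-focused   — markers U·Λ and V (genotype distances meaningful),
* environment-focused — markers U and V·Λ (environment vector lengths
  meaningful),
* symmetric          — Λ^0.5 to each side.

In every mode the inner product of a genotype and an environment marker
reconstructs the rank-2 approximation of the centered table, which is
what the which-won-where geometry exploits: the winner of an environment
is the genotype maximizing that inner product, necessarily a vertex of
the convex hull of genotype markers.

The average environment coordinate (AEC) is the direction of the mean
environment marker.  Projections onto it read mean performance; the
perpendicular component reads instability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .met_core import TwoWayTable

__all__ = [
    "GGEModel",
    "AEC",
    "MegaEnvironmentPartition",
    "fit_gge",
    "which_won_where",
    "mean_vs_stability",
    "rank_genotypes",
    "discrimination_representativeness",
]

SVP_MODES = ("genotype", "environment", "symmetric")
SCALING_MODES = ("none", "sd")


@dataclass
class GGEModel:
    """Environment-centered SVD of a two-way table with rank-2 markers."""

    trait: str
    genotypes: list[str]
    environments: list[str]
    centered: np.ndarray
    singular_values: np.ndarray
    genotype_scores: np.ndarray      # g × rank, orthonormal columns
    environment_scores: np.ndarray   # e × rank, orthonormal columns
    svp_mode: str
    scaling_mode: str

    @property
    def rank(self) -> int:
        return len(self.singular_values)

    @property
    def goodness_of_fit(self) -> float:
        """Share of total G+GE sum of squares captured by the first two axes."""
        total = float((self.singular_values ** 2).sum())
        if total == 0.0:
            return 1.0
        return float((self.singular_values[:2] ** 2).sum()) / total

    def _marker_scales(self) -> tuple[np.ndarray, np.ndarray]:
        lam = self.singular_values[:2]
        if self.svp_mode == "genotype":
            return lam, np.ones_like(lam)
        if self.svp_mode == "environment":
            return np.ones_like(lam), lam
        return np.sqrt(lam), np.sqrt(lam)

    @property
    def genotype_markers(self) -> np.ndarray:
        gscale, _ = self._marker_scales()
        return self.genotype_scores[:, :2] * gscale

    @property
    def environment_markers(self) -> np.ndarray:
        _, escale = self._marker_scales()
        return self.environment_scores[:, :2] * escale


@dataclass(frozen=True)
class AEC:
    """Average environment coordinate axis in the rank-2 marker plane."""

    direction: np.ndarray                      # unit 2-vector
    genotype_mean_projection: np.ndarray       # signed, along the AEC
    genotype_stability_projection: np.ndarray  # signed, perpendicular

    @property
    def ordinate(self) -> np.ndarray:
        """Unit vector perpendicular to the AEC (90° counterclockwise)."""
        return np.array([-self.direction[1], self.direction[0]])


@dataclass
class MegaEnvironmentPartition:
    """Which-won-where sectors: hull vertices and their environments."""

    sectors: list[tuple[str, list[str]]]
    hull: list[str]

    def winner_of(self, environment: str) -> str:
        for vertex, envs in self.sectors:
            if environment in envs:
                return vertex
        raise KeyError(environment)


def fit_gge(
    table: TwoWayTable, scaling: str = "none", svp: str = "symmetric"
) -> GGEModel:
    """Environment-center (optionally sd-scale) the table and decompose it."""
    if scaling not in SCALING_MODES:
        raise ValueError(f"scaling must be one of {SCALING_MODES}")
    if svp not in SVP_MODES:
        raise ValueError(f"svp must be one of {SVP_MODES}")
    g, e = table.n_genotypes, table.n_environments
    if g < 3 or e < 3:
        raise ValueError("GGE needs at least 3 genotypes and 3 environments")
    centered = table.means - table.environment_means[None, :]
    if scaling == "sd":
        sds = table.means.std(axis=0, ddof=1)
        zero = np.flatnonzero(sds == 0)
        if zero.size:
            raise ValueError(
                f"environment {table.environments[zero[0]]!r} has zero variance; "
                "sd-scaling undefined"
            )
        centered = centered / sds[None, :]
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    v = vt.T
    for k in range(v.shape[1]):  # orient columns deterministically
        j = int(np.argmax(np.abs(v[:, k])))
        if v[j, k] < 0:
            v[:, k] = -v[:, k]
            u[:, k] = -u[:, k]
    rank = min(g - 1, e)  # column centering annihilates the genotype intercept
    return GGEModel(
        trait=table.trait,
        genotypes=list(table.genotypes),
        environments=list(table.environments),
        centered=centered,
        singular_values=s[:rank],
        genotype_scores=u[:, :rank],
        environment_scores=v[:, :rank],
        svp_mode=svp,
        scaling_mode=scaling,
    )


def _require_2d(model: GGEModel) -> None:
    gm = model.genotype_markers
    spread = gm - gm.mean(axis=0)
    sv = np.linalg.svd(spread, compute_uv=False)
    if sv[0] == 0.0 or sv[1] / sv[0] < 1e-5:
        raise ValueError(
            "genotype markers are collinear; the 2-D biplot geometry is "
            "degenerate (check the rank of the centered matrix)"
        )


def which_won_where(model: GGEModel) -> MegaEnvironmentPartition:
    """Convex-hull sectoring of the biplot: who wins in which environments.

    The plane is partitioned by rays perpendicular to the hull edges;
    equivalently (and exactly), each environment's winner is the hull
    vertex maximizing the marker inner product, i.e. the genotype with
    the largest rank-2 reconstructed G+GE value in that environment.
    Boundary ties are broken toward the counterclockwise-first vertex.
    """
    _require_2d(model)
    gm = model.genotype_markers
    em = model.environment_markers
    try:
        hull = ConvexHull(gm)
    except QhullError as exc:
        raise ValueError(
            "degenerate genotype-marker geometry; convex hull undefined"
        ) from exc
    hull_idx = list(hull.vertices)  # counterclockwise order
    hull_labels = [model.genotypes[i] for i in hull_idx]

    scores = gm @ em.T  # g × e rank-2 reconstruction
    winners: list[int] = []
    for j in range(len(model.environments)):
        col = scores[:, j]
        best = np.flatnonzero(col == col.max())
        # ties: prefer the counterclockwise-first hull vertex
        on_hull = [i for i in hull_idx if i in best]
        winners.append(on_hull[0] if on_hull else int(best[0]))

    sectors = []
    for i, label in zip(hull_idx, hull_labels):
        envs = [model.environments[j] for j, w in enumerate(winners) if w == i]
        sectors.append((label, envs))
    return MegaEnvironmentPartition(sectors=sectors, hull=hull_labels)


def _aec(model: GGEModel) -> AEC:
    em = model.environment_markers
    mean_marker = em.mean(axis=0)
    norm = np.linalg.norm(mean_marker)
    if norm < 1e-12:
        raise ValueError(
            "mean environment marker is at the origin; the AEC direction is "
            "undefined (data may be interaction-dominated)"
        )
    d = mean_marker / norm
    gm = model.genotype_markers
    proj = gm @ d
    perp_axis = np.array([-d[1], d[0]])
    perp = gm @ perp_axis
    return AEC(
        direction=d,
        genotype_mean_projection=proj,
        genotype_stability_projection=perp,
    )


def mean_vs_stability(model: GGEModel) -> tuple[AEC, pd.DataFrame]:
    """Mean-performance vs stability view along the AEC.

    A genotype's signed projection on the AEC reads its mean performance;
    the magnitude of the perpendicular component reads its instability.
    Returned frame is sorted by descending projection, then stability.
    """
    aec = _aec(model)
    df = pd.DataFrame(
        {
            "mean_projection": aec.genotype_mean_projection,
            "stability": np.abs(aec.genotype_stability_projection),
        },
        index=pd.Index(model.genotypes, name="genotype"),
    )
    df["mean_rank"] = df["mean_projection"].rank(ascending=False, method="first").astype(int)
    df["stability_rank"] = df["stability"].rank(ascending=True, method="first").astype(int)
    return aec, df.sort_values(["mean_projection", "stability"], ascending=[False, True])


def rank_genotypes(model: GGEModel) -> pd.DataFrame:
    """Rank genotypes by distance to the ideal point on the AEC.

    The ideal point sits on the positive AEC direction at the largest
    genotype projection; genotypes are ranked by ascending Euclidean
    distance from it (1 = closest to ideal).
    """
    aec = _aec(model)
    gm = model.genotype_markers
    ideal = aec.direction * aec.genotype_mean_projection.max()
    dist = np.linalg.norm(gm - ideal, axis=1)
    df = pd.DataFrame(
        {"distance_to_ideal": dist},
        index=pd.Index(model.genotypes, name="genotype"),
    )
    df["rank"] = df["distance_to_ideal"].rank(method="first").astype(int)
    return df.sort_values("distance_to_ideal")


def discrimination_representativeness(model: GGEModel) -> pd.DataFrame:
    """Environment vector lengths and angles with the AEC.

    ``vector_length`` (discriminativeness) is the marker norm — under
    environment-focused SVP its square approximates the environment's
    share of G+GE captured in rank 2.  ``cos_angle`` with the AEC reads
    representativeness.  The environment maximizing the product of the
    two is flagged as the ideal test environment.
    """
    aec = _aec(model)
    em = model.environment_markers
    length = np.linalg.norm(em, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos = np.where(length > 0, em @ aec.direction / length, np.nan)
    df = pd.DataFrame(
        {"vector_length": length, "cos_angle": cos},
        index=pd.Index(model.environments, name="environment"),
    )
    df["score"] = df["vector_length"] * df["cos_angle"]
    df["ideal_test_env"] = False
    if df["score"].notna().any():
        df.loc[df["score"].idxmax(), "ideal_test_env"] = True
    return df
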