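"""Pairwise Pearson correlation among traits with significance flags.

The default basis is the set of g × e genotype-by-environment cell means
pooled across environments, so each trait contributes one observation
per genotype × environment combination.  Plot-level and genotype-mean
bases are available.  Two-sided p-values come from the t transform
t = r·sqrt((n−2)/(1−r²)) with n − 2 df; no multiple-testing adjustment
is applied by default, with Bonferroni available by flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .met_core import EnvironmentCoding, METDataset, cell_means

logger = logging.getLogger(__name__)

__all__ = ["CorrelationMatrix", "pearson_matrix"]

BASES = ("cell-means", "genotype-means", "plot")


@dataclass
class CorrelationMatrix:
    """Symmetric trait × trait Pearson correlations with p-values."""

    traits: list[str]
    r: pd.DataFrame
    p: pd.DataFrame
    n: int
    basis: str

    def stars(self) -> pd.DataFrame:
        from .pooled_anova import significance_stars

        out = self.p.copy().astype(object)
        for a in self.traits:
            for b in self.traits:
                out.loc[a, b] = (
                    "" if a == b or pd.isna(self.p.loc[a, b])
                    else significance_stars(float(self.p.loc[a, b]))
                )
        return out


def _trait_vectors(
    data: METDataset,
    traits: Sequence[str],
    basis: str,
    coding: EnvironmentCoding | None,
) -> pd.DataFrame:
    if basis == "plot":
        wide = data.frame.pivot_table(
            index=["genotype", "location", "year", "rep"],
            columns="trait", values="value", sort=False,
        )
        return wide[list(traits)]
    vectors = {}
    for trait in traits:
        table = cell_means(data, trait, coding)
        if basis == "cell-means":
            vectors[trait] = table.means.ravel()
        else:  # genotype-means
            vectors[trait] = table.genotype_means
    return pd.DataFrame(vectors)


def pearson_matrix(
    data: METDataset,
    traits: Sequence[str] | None = None,
    basis: str = "cell-means",
    coding: EnvironmentCoding | None = None,
    bonferroni: bool = False,
) -> CorrelationMatrix:
    """Pearson correlation matrix among traits on the chosen basis.

    A zero-variance trait yields NaN correlations with a warning rather
    than an error.  With ``bonferroni`` the p-values are multiplied by
    the number of distinct trait pairs (capped at 1).
    """
    if basis not in BASES:
        raise ValueError(f"basis must be one of {BASES}")
    traits = list(traits) if traits is not None else data.traits
    if len(traits) < 2:
        raise ValueError("need at least two traits to correlate")
    obs = _trait_vectors(data, traits, basis, coding)
    n = len(obs)
    if n < 3:
        raise ValueError("need at least 3 paired observations per trait pair")

    values = obs.to_numpy(dtype=float)
    sds = values.std(axis=0, ddof=1)
    degenerate = [t for t, s in zip(traits, sds) if s == 0]
    if degenerate:
        logger.warning("zero-variance trait(s) %s: correlations undefined", degenerate)

    k = len(traits)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    for a in range(k):
        for b in range(k):
            if sds[a] == 0 or sds[b] == 0:
                continue
            if a == b:
                r[a, b] = 1.0
                continue
            xa, xb = values[:, a], values[:, b]
            cov = float(((xa - xa.mean()) * (xb - xb.mean())).sum()) / (n - 1)
            r_ab = cov / (sds[a] * sds[b])
            r_ab = min(1.0, max(-1.0, r_ab))
            r[a, b] = r_ab
            if abs(r_ab) < 1.0:
                t = r_ab * np.sqrt((n - 2) / (1.0 - r_ab ** 2))
                p[a, b] = 2.0 * float(stats.t.sf(abs(t), n - 2))
            else:
                p[a, b] = 0.0
    if bonferroni:
        m = k * (k - 1) / 2
        p = np.minimum(p * m, 1.0)
    idx = pd.Index(traits, name="trait")
    return CorrelationMatrix(
        traits=traits,
        r=pd.DataFrame(r, index=idx, columns=idx),
        p=pd.DataFrame(p, index=idx, columns=idx),
        n=n,
        basis=basis,
    )
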