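"""Fixed-effects ANOVA for balanced MET data.

Two partitions are provided:

``pooled_anova``
    The combined plot-level ANOVA over genotype, location and year with
    all their interactions (G, L, Y, G×Y, G×L, Y×L, G×Y×L) against the
    pooled replicate error — the classical first look at a MET.

``env_collapsed_anova``
    The G / E / G×E partition obtained after coding each location × year
    combination as one environment; this is the table the AMMI
    decomposition refines.  It can be expressed on the plot basis
    (means-based SS × r, error from the pooled within-cell MS) or on the
    cell-means basis.

Everything is computed as fixed effects: only sums of squares, mean
squares and F ratios are reported, which coincide with the random-effects
quantities for a balanced design.  Replicate blocks are pooled into
error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .met_core import METDataset, TwoWayTable

__all__ = [
    "AnovaRow",
    "AnovaTable",
    "pooled_anova",
    "env_collapsed_anova",
    "percent_explained",
    "significance_stars",
]


def percent_explained(ss: dict[str, float]) -> dict[str, float]:
    """Share (%) of each component in the summed SS of the given components."""
    total = sum(ss.values())
    if total <= 0:
        raise ValueError("total sum of squares must be positive")
    return {k: 100.0 * v / total for k, v in ss.items()}


def significance_stars(p: float | None) -> str:
    """Conventional significance stars at 0.05 / 0.01 / 0.001."""
    if p is None or np.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class AnovaRow:
    source: str
    df: int
    ss: float
    ms: float | None = None
    f: float | None = None
    p: float | None = None
    pct_explained: float | None = None

    def __post_init__(self) -> None:
        if self.ms is None and self.df > 0:
            self.ms = self.ss / self.df


@dataclass
class AnovaTable:
    """Ordered ANOVA rows plus the basis (plot or means) they live on."""

    rows: list[AnovaRow]
    basis: str = "plot"

    def __getitem__(self, source: str) -> AnovaRow:
        for row in self.rows:
            if row.source == source:
                return row
        raise KeyError(source)

    @property
    def sources(self) -> list[str]:
        return [r.source for r in self.rows]

    def to_frame(self, round_to: int | None = 2) -> pd.DataFrame:
        recs = []
        for r in self.rows:
            recs.append(
                {
                    "source": r.source,
                    "df": r.df,
                    "ss": r.ss,
                    "ms": r.ms,
                    "f": r.f,
                    "p": r.p,
                    "pct_explained": r.pct_explained,
                    "sig": significance_stars(r.p) if r.p is not None else "",
                }
            )
        df = pd.DataFrame(recs)
        for col in ("ss", "ms", "f", "p", "pct_explained"):
            df[col] = pd.to_numeric(df[col], errors="coerce")
            if round_to is not None and col != "p":
                df[col] = df[col].round(round_to)
        return df


def _f_test(ms: float, error_ms: float, df: int, error_df: int):
    if error_df <= 0 or error_ms <= 0:
        return None, None
    f = ms / error_ms
    p = float(stats.f.sf(f, df, error_df))
    return f, p


def pooled_anova(data: METDataset, trait: str) -> AnovaTable:
    """Combined G × L × Y factorial ANOVA on plot-level data.

    Requires a balanced design; with r = 1 there is no error df and F/p
    are omitted.  All factorial terms are tested against the pooled
    replicate error.
    """
    if trait not in data.traits:
        raise KeyError(f"unknown trait {trait!r}")
    sub = data.frame[data.frame["trait"] == trait]
    genotypes = list(dict.fromkeys(sub["genotype"]))
    locations = list(dict.fromkeys(sub["location"]))
    years = list(dict.fromkeys(sub["year"]))
    g, l, y, r = len(genotypes), len(locations), len(years), data.n_replicates

    values = np.full((g, l, y, r), np.nan)
    gi = {k: i for i, k in enumerate(genotypes)}
    li = {k: i for i, k in enumerate(locations)}
    yi = {k: i for i, k in enumerate(years)}
    rep_seen: dict[tuple, int] = {}
    for rec in sub.itertuples(index=False):
        cell = (gi[rec.genotype], li[rec.location], yi[rec.year])
        k = rep_seen.get(cell, 0)
        rep_seen[cell] = k + 1
        values[cell + (k,)] = rec.value
    assert not np.isnan(values).any(), "balance validation should preclude holes"

    cells = values.mean(axis=3)          # g × l × y cell means
    grand = cells.mean()
    m_g = cells.mean(axis=(1, 2))
    m_l = cells.mean(axis=(0, 2))
    m_y = cells.mean(axis=(0, 1))
    m_gl = cells.mean(axis=2)
    m_gy = cells.mean(axis=1)
    m_ly = cells.mean(axis=0)

    ss_g = l * y * r * float(((m_g - grand) ** 2).sum())
    ss_l = g * y * r * float(((m_l - grand) ** 2).sum())
    ss_y = g * l * r * float(((m_y - grand) ** 2).sum())
    ss_gl = y * r * float(
        ((m_gl - m_g[:, None] - m_l[None, :] + grand) ** 2).sum()
    )
    ss_gy = l * r * float(
        ((m_gy - m_g[:, None] - m_y[None, :] + grand) ** 2).sum()
    )
    ss_ly = g * r * float(
        ((m_ly - m_l[:, None] - m_y[None, :] + grand) ** 2).sum()
    )
    resid3 = (
        cells
        - m_gl[:, :, None]
        - m_gy[:, None, :]
        - m_ly[None, :, :]
        + m_g[:, None, None]
        + m_l[None, :, None]
        + m_y[None, None, :]
        - grand
    )
    ss_gly = r * float((resid3 ** 2).sum())
    ss_err = float(((values - cells[..., None]) ** 2).sum())
    df_err = g * l * y * (r - 1)
    ms_err = ss_err / df_err if df_err > 0 else 0.0

    spec: list[tuple[str, int, float]] = [
        ("Genotype", g - 1, ss_g),
        ("Location", l - 1, ss_l),
        ("Year", y - 1, ss_y),
        ("G x Y", (g - 1) * (y - 1), ss_gy),
        ("G x L", (g - 1) * (l - 1), ss_gl),
        ("Y x L", (y - 1) * (l - 1), ss_ly),
        ("G x Y x L", (g - 1) * (l - 1) * (y - 1), ss_gly),
    ]
    rows = []
    for source, df, ss in spec:
        row = AnovaRow(source, df, ss)
        if df > 0:
            row.f, row.p = _f_test(row.ms, ms_err, df, df_err)
        rows.append(row)
    rows.append(AnovaRow("Error", df_err, ss_err, ms=ms_err if df_err else None))
    total_ss = sum(r_.ss for r_ in rows)
    rows.append(AnovaRow("Total", g * l * y * r - 1, total_ss, ms=None))
    rows[-1].ms = None
    return AnovaTable(rows=rows, basis="plot")


def env_collapsed_anova(
    table: TwoWayTable,
    basis: str = "plot",
    test_g_over_ge: bool = False,
) -> AnovaTable:
    """G / E / G×E partition of a two-way table.

    On the plot basis the means-based SS are multiplied by the replicate
    count and tested against the pooled within-cell error; on the means
    basis SS stay on the cell-mean scale and no F is attached.  The
    percentage explained by each of G, E and G×E is relative to their
    sum (error excluded), matching how MET reports quote contributions.
    """
    if basis not in ("plot", "means"):
        raise ValueError("basis must be 'plot' or 'means'")
    g, e, r = table.n_genotypes, table.n_environments, table.replicates
    scale = r if basis == "plot" else 1

    ss_g = scale * e * float(((table.genotype_means - table.grand_mean) ** 2).sum())
    ss_e = scale * g * float(((table.environment_means - table.grand_mean) ** 2).sum())
    ss_ge = scale * float((table.interaction_residuals() ** 2).sum())
    total_model = ss_g + ss_e + ss_ge

    rows = [
        AnovaRow("Environment", e - 1, ss_e),
        AnovaRow("Genotype", g - 1, ss_g),
        AnovaRow("G x E", (g - 1) * (e - 1), ss_ge),
    ]
    if total_model > 0:
        pct = percent_explained({row.source: row.ss for row in rows})
        for row in rows:
            row.pct_explained = pct[row.source]

    if basis == "plot" and r > 1:
        df_err = g * e * (r - 1)
        ms_err = table.pooled_error_ms
        for row in rows:
            if row.source == "Genotype" and test_g_over_ge:
                row.f, row.p = _f_test(row.ms, rows[2].ms, row.df, rows[2].df)
            else:
                row.f, row.p = _f_test(row.ms, ms_err, row.df, df_err)
        rows.append(AnovaRow("Error", df_err, ms_err * df_err, ms=ms_err))
    return AnovaTable(rows=rows, basis=basis)
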