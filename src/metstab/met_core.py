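"""Data model, validation and IO for balanced multi-environment trials (METs).

A MET evaluates a set of genotypes at several environments, where an
environment is a location × year combination, with replicated plots laid
out in randomized blocks.  All downstream analyses (pooled ANOVA,
joint-regression stability, AMMI, GGE) assume a *balanced* design: every
genotype is observed in every environment with the same number of
replicates.

Two containers do most of the work:

``METDataset``
    Tidy plot-level records, one row per
    (genotype, location, year, replicate, trait).

``TwoWayTable``
    The genotype × environment matrix of cell means for one trait,
    together with the replicate count and the pooled within-cell error
    mean square — the sufficient statistics for every model in this
    package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical long-format column names, in order
LONG_COLUMNS = ("genotype", "location", "year", "rep", "trait", "value")
KEY_COLUMNS = ("genotype", "location", "year", "rep", "trait")


class SchemaError(ValueError):
    """Input file or frame does not carry the required columns."""


class BalanceError(ValueError):
    """Design is not balanced; message lists the offending cells."""


class ParseError(ValueError):
    """A value field could not be parsed as a number."""


@dataclass(frozen=True)
class EnvironmentCoding:
    """Bijective coding of observed (location, year) pairs to ENV labels.

    The default convention enumerates locations within each year, so with
    four locations and two years ENV1–ENV4 are year 1 and ENV5–ENV8 are
    year 2 at the same four locations.
    """

    mapping: Mapping[tuple[str, str], str]
    ordering: tuple[str, ...]

    @classmethod
    def from_pairs(
        cls,
        pairs: Sequence[tuple[str, str]],
        location_order: Sequence[str] | None = None,
        prefix: str = "ENV",
    ) -> "EnvironmentCoding":
        """Build the default coding from observed (location, year) pairs.

        Years are sorted ascending; locations follow ``location_order`` if
        given, otherwise their order of first appearance in ``pairs``.
        """
        pairs = list(dict.fromkeys((str(l), str(y)) for l, y in pairs))
        years = sorted({y for _, y in pairs})
        if location_order is None:
            location_order = list(dict.fromkeys(l for l, _ in pairs))
        else:
            location_order = [str(l) for l in location_order]
            missing = {l for l, _ in pairs} - set(location_order)
            if missing:
                raise ValueError(f"location_order omits locations: {sorted(missing)}")
        mapping: dict[tuple[str, str], str] = {}
        k = 0
        for y in years:
            for l in location_order:
                if (l, y) in pairs:
                    k += 1
                    mapping[(l, y)] = f"{prefix}{k}"
        ordering = tuple(mapping[p] for p in sorted(mapping, key=lambda p: int(mapping[p][len(prefix):])))
        return cls(mapping=mapping, ordering=ordering)

    def label(self, location: str, year: str) -> str:
        return self.mapping[(str(location), str(year))]


@dataclass
class METDataset:
    """Validated plot-level MET records in long format.

    Attributes
    ----------
    frame : pandas.DataFrame
        Columns ``genotype, location, year, rep, trait, value``; keys are
        strings except ``rep`` (positive int) and ``value`` (float).
    """

    frame: pd.DataFrame

    # -- construction ------------------------------------------------------

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, impute: bool = False) -> "METDataset":
        """Validate (and optionally impute isolated missing plots in) a frame."""
        missing = set(LONG_COLUMNS) - set(frame.columns)
        if missing:
            raise SchemaError(f"missing required columns: {sorted(missing)}")
        df = frame.loc[:, list(LONG_COLUMNS)].copy()
        for col in ("genotype", "location", "year", "trait"):
            df[col] = df[col].astype(str)
        try:
            df["rep"] = df["rep"].astype(int)
        except (TypeError, ValueError) as exc:
            raise ParseError(f"replicate column is not integer: {exc}") from exc
        if (df["rep"] < 1).any():
            raise ParseError("replicate numbers must be positive integers")
        try:
            df["value"] = pd.to_numeric(df["value"], errors="raise")
        except (TypeError, ValueError) as exc:
            raise ParseError(f"non-numeric trait value: {exc}") from exc

        dup = df.duplicated(subset=list(KEY_COLUMNS))
        if dup.any():
            keys = df.loc[dup, list(KEY_COLUMNS)].iloc[0].tolist()
            raise BalanceError(f"duplicate record key {tuple(keys)}")

        if impute:
            df = _impute_missing_plots(df)
        _check_balance(df)
        ds = cls(frame=df.reset_index(drop=True))
        if ds.n_genotypes < 2 or ds.n_environments < 2:
            raise BalanceError(
                f"need at least 2 genotypes and 2 environments, got "
                f"g={ds.n_genotypes}, e={ds.n_environments}"
            )
        return ds

    # -- basic properties --------------------------------------------------

    @property
    def genotypes(self) -> list[str]:
        return list(dict.fromkeys(self.frame["genotype"]))

    @property
    def traits(self) -> list[str]:
        return list(dict.fromkeys(self.frame["trait"]))

    @property
    def environment_pairs(self) -> list[tuple[str, str]]:
        seen = self.frame[["location", "year"]].drop_duplicates()
        return [tuple(r) for r in seen.itertuples(index=False)]

    @property
    def n_genotypes(self) -> int:
        return len(self.genotypes)

    @property
    def n_environments(self) -> int:
        return len(self.environment_pairs)

    @property
    def n_replicates(self) -> int:
        counts = self.frame.groupby(
            ["trait", "genotype", "location", "year"], sort=False
        ).size()
        return int(counts.iloc[0])

    def default_coding(
        self, location_order: Sequence[str] | None = None
    ) -> EnvironmentCoding:
        return EnvironmentCoding.from_pairs(self.environment_pairs, location_order)


def _check_balance(df: pd.DataFrame) -> None:
    """Every genotype × location × year cell must have the same replicate count."""
    for trait, sub in df.groupby("trait", sort=False):
        genotypes = sub["genotype"].unique()
        cells = sub.groupby(["location", "year"], sort=False)
        counts = sub.groupby(["genotype", "location", "year"], sort=False).size()
        r = counts.iloc[0]
        bad = counts[counts != r]
        expected = {(g, l, y) for g in genotypes for (l, y), _ in cells}
        observed = set(counts.index)
        absent = expected - observed
        if len(bad) or absent:
            offenders = sorted(absent) + [tuple(k) for k in bad.index]
            raise BalanceError(
                f"trait {trait!r}: unbalanced design; offending "
                f"(genotype, location, year) cells: {offenders[:10]}"
            )


def _impute_missing_plots(df: pd.DataFrame) -> pd.DataFrame:
    """Fill isolated missing plots with the mean of the cell's remaining reps."""
    filled = []
    n_imputed = 0
    for trait, sub in df.groupby("trait", sort=False):
        counts = sub.groupby(["genotype", "location", "year"], sort=False).size()
        r = int(counts.max())
        reps = set(range(1, r + 1))
        for (g, l, y), cell in sub.groupby(["genotype", "location", "year"], sort=False):
            have = set(cell["rep"])
            for rep in sorted(reps - have):
                if len(cell) == 0:
                    raise BalanceError(
                        f"cell (genotype={g}, location={l}, year={y}) for trait "
                        f"{trait!r} is entirely missing; cannot impute"
                    )
                filled.append((g, l, y, rep, trait, float(cell["value"].mean())))
                n_imputed += 1
    if n_imputed:
        logger.warning("imputed %d missing plot(s) with cell means", n_imputed)
        extra = pd.DataFrame(filled, columns=list(LONG_COLUMNS))
        df = pd.concat([df, extra], ignore_index=True)
    return df


# -- IO --------------------------------------------------------------------


def read_met(
    path: str | Path,
    sep: str | None = None,
    impute: bool = False,
) -> METDataset:
    """Read a delimited MET file (long or wide trait layout) into a dataset.

    Long layout carries ``trait`` and ``value`` columns; wide layout carries
    one column per trait next to the four key columns and is melted to long.
    The delimiter is auto-detected (comma or tab) unless ``sep`` is given.
    """
    path = Path(path)
    if sep is None:
        header = path.open(encoding="utf-8").readline()
        sep = "\t" if header.count("\t") >= header.count(",") else ","
    try:
        df = pd.read_csv(path, sep=sep, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"could not parse {path}: {exc}") from exc
    df.columns = [c.strip().lower() for c in df.columns]

    key_cols = {"genotype", "location", "year", "rep"}
    if not key_cols <= set(df.columns):
        raise SchemaError(
            f"{path} is missing key columns {sorted(key_cols - set(df.columns))}"
        )
    if not {"trait", "value"} <= set(df.columns):
        trait_cols = [c for c in df.columns if c not in key_cols]
        if not trait_cols:
            raise SchemaError(f"{path} carries no trait columns")
        df = df.melt(
            id_vars=sorted(key_cols), value_vars=trait_cols,
            var_name="trait", value_name="value",
        )
    for i, v in enumerate(df["value"]):
        try:
            float(v)
        except (TypeError, ValueError):
            raise ParseError(
                f"{path}: non-numeric value {v!r} in record {i + 1}"
            ) from None
    return METDataset.from_frame(df, impute=impute)


def write_met(data: METDataset, path: str | Path, sep: str = "\t") -> None:
    """Write the dataset as delimited long-format text (round-trip stable)."""
    df = data.frame.copy()
    df["value"] = [repr(float(v)) for v in df["value"]]
    df.to_csv(path, sep=sep, index=False)


# -- two-way tables --------------------------------------------------------


@dataclass
class TwoWayTable:
    """Genotype × environment cell-mean matrix for one trait.

    ``means[i, j]`` is x_ij, the mean over replicates of genotype i in
    environment j.  ``pooled_error_ms`` is the within-cell error mean
    square on the plot basis, SS(within) / (g·e·(r−1)); replication blocks
    are pooled into it.
    """

    trait: str
    genotypes: list[str]
    environments: list[str]
    means: np.ndarray
    replicates: int
    pooled_error_ms: float
    grand_mean: float = field(init=False)
    genotype_means: np.ndarray = field(init=False)
    environment_means: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        g, e = self.means.shape
        if g != len(self.genotypes) or e != len(self.environments):
            raise ValueError("means shape does not match label lengths")
        self.grand_mean = float(self.means.mean())
        self.genotype_means = self.means.mean(axis=1)
        self.environment_means = self.means.mean(axis=0)

    @property
    def n_genotypes(self) -> int:
        return len(self.genotypes)

    @property
    def n_environments(self) -> int:
        return len(self.environments)

    def interaction_residuals(self) -> np.ndarray:
        """Double-centered matrix z_ij = x_ij − X_i. − X_.j + X.. ."""
        return (
            self.means
            - self.genotype_means[:, None]
            - self.environment_means[None, :]
            + self.grand_mean
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.means, index=self.genotypes, columns=self.environments)


def cell_means(
    data: METDataset,
    trait: str,
    coding: EnvironmentCoding | None = None,
) -> TwoWayTable:
    """Average replicates into a genotype × environment table for one trait.

    The pooled error mean square is the within-cell deviation SS divided by
    g·e·(r−1).  With a single replicate it is reported as 0 with a warning,
    because no within-cell error df exist.
    """
    if trait not in data.traits:
        raise KeyError(f"unknown trait {trait!r}; available: {data.traits}")
    if coding is None:
        coding = data.default_coding()
    sub = data.frame[data.frame["trait"] == trait].copy()
    sub["env"] = [coding.label(l, y) for l, y in zip(sub["location"], sub["year"])]

    genotypes = list(dict.fromkeys(sub["genotype"]))
    environments = list(coding.ordering)
    r = data.n_replicates

    pivot = sub.pivot_table(index="genotype", columns="env", values="value", aggfunc="mean")
    means = pivot.loc[genotypes, environments].to_numpy(dtype=float)

    if r > 1:
        cell_mean = sub.groupby(["genotype", "env"], sort=False)["value"].transform("mean")
        ss_within = float(((sub["value"] - cell_mean) ** 2).sum())
        mse = ss_within / (len(genotypes) * len(environments) * (r - 1))
    else:
        logger.warning(
            "trait %r has a single replicate; pooled error MS set to 0", trait
        )
        mse = 0.0
    return TwoWayTable(
        trait=trait,
        genotypes=genotypes,
        environments=environments,
        means=means,
        replicates=r,
        pooled_error_ms=mse,
    )


def write_table(table: TwoWayTable, path: str | Path, sep: str = "\t") -> None:
    """Write a two-way table as labeled delimited text."""
    table.to_frame().to_csv(path, sep=sep, index_label="genotype")
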