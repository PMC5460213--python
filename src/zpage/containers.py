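"""Core in-memory containers: expression matrices, z-score matrices, gene sets.

Expression values are raw (strictly positive) hybridization intensities,
genes in rows and samples (arrays) in columns.  Each sample carries a
species tag and an age-group label (young / middle / old).  Gene symbols are
case-insensitive throughout: mixed mouse/human casing (``Actb`` vs ``ACTB``)
is unavoidable in cross-species work, so symbols are upper-cased once at
container construction and compared verbatim afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

AGE_GROUPS = ("young", "middle", "old")


def normalize_symbol(symbol: str) -> str:
    """Case-fold a gene symbol to its canonical (upper-case) form."""
    return str(symbol).strip().upper()


def _check_unique_symbols(symbols: Iterable[str]) -> list[str]:
    canonical = [normalize_symbol(s) for s in symbols]
    seen: dict[str, int] = {}
    dupes = []
    for s in canonical:
        seen[s] = seen.get(s, 0) + 1
        if seen[s] == 2:
            dupes.append(s)
    if dupes:
        raise ValueError(
            "duplicate gene symbols after case normalization: "
            + ", ".join(sorted(dupes)[:10])
        )
    return canonical


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of strictly positive raw intensities.

    Parameters
    ----------
    values : DataFrame
        Rows indexed by gene symbol, columns by sample ID.
    species : str
        Species label shared by all samples in the matrix.
    age_groups : mapping
        Sample ID -> one of ``young``, ``middle``, ``old``.
    """

    values: pd.DataFrame
    species: str
    age_groups: Mapping[str, str]

    def __post_init__(self) -> None:
        canonical = _check_unique_symbols(self.values.index)
        self.values = self.values.copy()
        self.values.index = pd.Index(canonical, name="gene_symbol")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample IDs")
        arr = self.values.to_numpy(dtype=float)
        if np.isnan(arr).any():
            g, s = np.argwhere(np.isnan(arr))[0]
            raise ValueError(
                f"missing value at gene {self.values.index[g]!r}, "
                f"sample {self.values.columns[s]!r}"
            )
        if (arr <= 0).any():
            g, s = np.argwhere(arr <= 0)[0]
            raise ValueError(
                f"nonpositive intensity at gene {self.values.index[g]!r}, "
                f"sample {self.values.columns[s]!r}: ln is undefined"
            )
        self.age_groups = dict(self.age_groups)
        missing = [s for s in self.values.columns if s not in self.age_groups]
        if missing:
            raise ValueError(f"samples without an age group: {missing}")
        bad = {s: g for s, g in self.age_groups.items() if g not in AGE_GROUPS}
        if bad:
            raise ValueError(f"unknown age groups: {bad}")

    @property
    def gene_symbols(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def samples_in_group(self, group: str) -> list[str]:
        """Sample IDs belonging to one age group, in column order."""
        if group not in AGE_GROUPS:
            raise ValueError(f"unknown age group {group!r}")
        return [s for s in self.values.columns if self.age_groups[s] == group]


@dataclass
class ZScoreMatrix:
    """Per-array z-scored ln intensities (dimensionless), same axes as input.

    ``array_means`` and ``array_sds`` retain the per-array ln-scale mean and
    sample SD removed by the normalization, so the transform is invertible.
    """

    values: pd.DataFrame
    species: str
    age_groups: Mapping[str, str]
    array_means: pd.Series = field(repr=False, default=None)
    array_sds: pd.Series = field(repr=False, default=None)

    @property
    def gene_symbols(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def samples_in_group(self, group: str) -> list[str]:
        if group not in AGE_GROUPS:
            raise ValueError(f"unknown age group {group!r}")
        return [s for s in self.values.columns if self.age_groups[s] == group]


@dataclass
class GeneSetCollection:
    """Named gene sets (a C2-style curated collection).

    ``sets`` maps set name -> tuple of unique, case-normalized member
    symbols; ``descriptions`` carries the GMT description field.
    """

    sets: dict[str, tuple[str, ...]]
    descriptions: dict[str, str] = field(default_factory=dict)
    source: str = ""

    def __post_init__(self) -> None:
        cleaned: dict[str, tuple[str, ...]] = {}
        for name, members in self.sets.items():
            canon = []
            seen = set()
            for m in members:
                c = normalize_symbol(m)
                if c not in seen:
                    seen.add(c)
                    canon.append(c)
            if not canon:
                raise ValueError(f"gene set {name!r} is empty")
            cleaned[name] = tuple(canon)
        self.sets = cleaned
        self.descriptions = {
            name: self.descriptions.get(name, "") for name in self.sets
        }

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def members(self, name: str) -> tuple[str, ...]:
        return self.sets[name]

    @property
    def names(self) -> list[str]:
        return list(self.sets)
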