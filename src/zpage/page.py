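"""PAGE: parametric analysis of gene set enrichment.

For one contrast, let the per-gene scores be the Z-ratios of all genes on
the array, mu their mean and delta their sample SD.  For a gene set with m
member symbols present on the array and mean member score sm, the set-level
statistic is

    Z = (sm - mu) * sqrt(m) / delta

which is approximately standard normal for random sets when m is not tiny,
so a two-sided normal p-value p = 2 (1 - Phi(|Z|)) is attached.  Sets with
fewer than ``min_set_size`` members present are dropped before scoring
(the normal approximation degrades for very small m).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import GeneSetCollection, normalize_symbol

DEFAULT_MIN_SET_SIZE = 5
DEFAULT_ALPHA = 0.05
CORRECTIONS = ("none", "BH")


def map_sets_to_array(
    collection: GeneSetCollection,
    array_symbols: Iterable[str],
    min_set_size: int = DEFAULT_MIN_SET_SIZE,
) -> tuple[GeneSetCollection, pd.DataFrame]:
    """Restrict every set to symbols present on the array.

    Returns the filtered collection (sets with fewer than ``min_set_size``
    present members removed) and a report frame listing every input set
    with its original size, present count m, and whether it was retained.
    A hard error is raised when the collection shares no symbols at all
    with the array — that pattern indicates a symbol-convention mismatch
    rather than genuine absence.
    """
    symbols = list(array_symbols)
    on_array = {normalize_symbol(s) for s in symbols}
    if len(on_array) != len(symbols):
        raise ValueError("array symbols not unique after case normalization")
    rows = []
    kept: dict[str, tuple[str, ...]] = {}
    any_overlap = False
    for name in collection.names:
        members = collection.members(name)
        present = tuple(m for m in members if m in on_array)
        if present:
            any_overlap = True
        retained = len(present) >= min_set_size
        rows.append(
            {
                "set": name,
                "size": len(members),
                "m": len(present),
                "retained": retained,
            }
        )
        if retained:
            kept[name] = present
    if not any_overlap:
        raise ValueError(
            "no overlap between collection and array symbols — "
            "likely a gene symbol convention mismatch"
        )
    report = pd.DataFrame(rows).set_index("set")
    filtered = GeneSetCollection(
        sets=kept,
        descriptions={n: collection.descriptions.get(n, "") for n in kept},
        source=collection.source,
    )
    return filtered, report


def page_z(gene_scores: pd.Series, members: Iterable[str]) -> float:
    """Set-level Z for one gene set against the whole-array score distribution."""
    mu = float(gene_scores.mean())
    delta = float(gene_scores.std(ddof=1))
    if delta == 0 or not np.isfinite(delta):
        raise ValueError("degenerate gene scores: zero spread across the array")
    present = [m for m in members if m in gene_scores.index]
    m = len(present)
    if m < 1:
        raise ValueError("no set members present among the gene scores")
    sm = float(gene_scores.loc[present].mean())
    return (sm - mu) * np.sqrt(m) / delta


def page_p(z: float | np.ndarray) -> float | np.ndarray:
    """Two-sided standard-normal p-value for a PAGE Z."""
    return 2.0 * stats.norm.sf(np.abs(z))


@dataclass
class PathwayScoreTable:
    """PAGE scores for every retained set of one contrast.

    ``table`` columns: m, sm, Z, p, direction; ``mu``/``delta`` are the
    whole-array score mean and sample SD shared by all rows.
    """

    table: pd.DataFrame
    mu: float
    delta: float
    species: str = ""
    contrast: tuple[str, str] | None = None
    min_set_size: int = DEFAULT_MIN_SET_SIZE
    dropped: pd.DataFrame | None = field(default=None, repr=False)


def score_sets(
    gene_scores: pd.Series,
    collection: GeneSetCollection,
    min_set_size: int = DEFAULT_MIN_SET_SIZE,
    species: str = "",
    contrast: tuple[str, str] | None = None,
) -> PathwayScoreTable:
    """Score every set of the collection against one contrast's gene scores.

    ``gene_scores`` is indexed by gene symbol (typically the Z-ratios of
    the contrast).  Vectorized equivalent of calling :func:`page_z` per set.
    """
    scores = gene_scores.astype(float)
    mu = float(scores.mean())
    delta = float(scores.std(ddof=1))
    if delta == 0 or not np.isfinite(delta):
        raise ValueError("degenerate gene scores: zero spread across the array")
    mapped, report = map_sets_to_array(collection, scores.index, min_set_size)
    rows = []
    for name in mapped.names:
        present = list(mapped.members(name))
        m = len(present)
        sm = float(scores.loc[present].mean())
        z = (sm - mu) * np.sqrt(m) / delta
        rows.append({"set": name, "m": m, "sm": sm, "Z": z})
    table = pd.DataFrame(rows).set_index("set") if rows else pd.DataFrame(
        columns=["m", "sm", "Z"]
    )
    table["p"] = page_p(table["Z"].to_numpy()) if len(table) else []
    table["direction"] = np.where(table["Z"] > 0, "up", "down") if len(table) else []
    return PathwayScoreTable(
        table=table,
        mu=mu,
        delta=delta,
        species=species,
        contrast=contrast,
        min_set_size=min_set_size,
        dropped=report[~report["retained"]],
    )


def call_significant_sets(
    table: PathwayScoreTable,
    alpha: float = DEFAULT_ALPHA,
    correction: str = "none",
) -> tuple[list[str], list[str]]:
    """Sorted (up, down) lists of sets significant at level alpha.

    up: p < alpha and Z > 0; down: p < alpha and Z < 0.  With
    ``correction="BH"`` the Benjamini–Hochberg step-up procedure is applied
    to the p-values before thresholding.
    """
    if not (0 < alpha < 1):
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    if correction not in CORRECTIONS:
        raise ValueError(f"unknown correction {correction!r}; use one of {CORRECTIONS}")
    t = table.table
    if not len(t):
        return [], []
    if correction == "BH":
        reject, _, _, _ = multipletests(t["p"].to_numpy(), alpha=alpha, method="fdr_bh")
        sig = pd.Series(reject, index=t.index)
    else:
        sig = t["p"] < alpha
    up = sorted(t.index[sig & (t["Z"] > 0)])
    down = sorted(t.index[sig & (t["Z"] < 0)])
    return up, down
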