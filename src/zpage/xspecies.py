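"""Cross-species intersection of significant pathway calls.

Pathway identity across species is by set name: the same collection is
scored against each species' contrast, and a pathway is *conserved* in a
direction when every species calls it significant in that direction — the
all-species region of the Venn diagram.  No ortholog mapping of member
symbols is performed; the collection itself is the common namespace.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import pandas as pd


@dataclass
class SpeciesPathwayCalls:
    """Significant pathway names per (species, contrast, direction).

    ``calls[(species, contrast, direction)]`` is a set of pathway names;
    up and down must be disjoint within a (species, contrast).
    """

    calls: dict[tuple[str, str, str], set[str]] = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)

    def add(
        self, species: str, contrast: str, direction: str, names: Iterable[str]
    ) -> None:
        if direction not in ("up", "down"):
            raise ValueError(f"direction must be up/down, got {direction!r}")
        key = (species, contrast, direction)
        other = (species, contrast, "down" if direction == "up" else "up")
        names = set(names)
        if other in self.calls and names & self.calls[other]:
            clash = sorted(names & self.calls[other])
            raise ValueError(
                f"sets called both up and down for {species}/{contrast}: {clash}"
            )
        self.calls[key] = names

    def get(self, species: str, contrast: str, direction: str) -> set[str]:
        key = (species, contrast, direction)
        if key not in self.calls:
            raise KeyError(
                f"no {direction} call list for species {species!r}, "
                f"contrast {contrast!r} — refusing to treat it as empty"
            )
        return set(self.calls[key])

    @property
    def species(self) -> list[str]:
        return sorted({k[0] for k in self.calls})


@dataclass
class VennReport:
    """Exact membership of every region of a k-way Venn diagram.

    ``regions`` maps a frozenset of species labels (the region: members of
    exactly those species' lists) to the sorted pathway names in it; empty
    regions are omitted.  Regions partition the union of the input lists.
    """

    species: tuple[str, ...]
    regions: dict[frozenset, tuple[str, ...]]

    def region(self, subset: Iterable[str]) -> tuple[str, ...]:
        return self.regions.get(frozenset(subset), ())

    @property
    def all_species_region(self) -> tuple[str, ...]:
        return self.region(self.species)

    @property
    def union_size(self) -> int:
        return sum(len(v) for v in self.regions.values())

    def to_frame(self) -> pd.DataFrame:
        """One row per (region, pathway), region labelled by species subset."""
        rows = []
        for r in range(len(self.species), 0, -1):
            for subset in combinations(self.species, r):
                names = self.regions.get(frozenset(subset), ())
                for name in names:
                    rows.append({"region": "&".join(subset), "pathway": name})
        return pd.DataFrame(rows, columns=["region", "pathway"])


def venn_regions(lists: Mapping[str, Iterable[str]]) -> VennReport:
    """Classify every pathway name into its exact Venn region.

    ``lists`` maps species label -> pathway names (2 to 4 species).  Each
    name in the union lands in exactly one region: the frozenset of species
    whose lists contain it.
    """
    species = list(lists)
    if len(species) != len(set(species)):
        raise ValueError("duplicate species labels")
    if not (2 <= len(species) <= 4):
        raise ValueError(f"venn_regions supports 2-4 species, got {len(species)}")
    sets = {sp: set(lists[sp]) for sp in species}
    regions: dict[frozenset, list[str]] = {}
    for name in set().union(*sets.values()):
        owners = frozenset(sp for sp in species if name in sets[sp])
        regions.setdefault(owners, []).append(name)
    return VennReport(
        species=tuple(species),
        regions={k: tuple(sorted(v)) for k, v in regions.items()},
    )


def conserved_pathways(
    calls: SpeciesPathwayCalls,
    direction: str,
    contrast: str = "old_vs_young",
    species: Sequence[str] | None = None,
    require_both_contrasts: bool = False,
) -> tuple[str, ...]:
    """Pathways significant in ``direction`` in every species.

    Intersects the per-species call lists for the given contrast; with
    ``require_both_contrasts`` a pathway must additionally be called in the
    same direction in the middle-age contrast.  A species without a call
    list raises — silently skipping one would change what "conserved in all
    species" means.
    """
    if species is None:
        species = calls.species
    if not species:
        raise ValueError("no species to intersect")
    out: set[str] | None = None
    for sp in species:
        names = calls.get(sp, contrast, direction)
        if require_both_contrasts:
            names &= calls.get(sp, "middle_vs_young", direction)
        out = names if out is None else out & names
    return tuple(sorted(out))
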