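"""Synthetic multi-species expression cohorts with planted pathway effects.

The generator emulates the structure of a four-species (mouse, rat, rhesus
monkey, human) skeletal-muscle aging study: three age groups per species,
strictly positive intensities, per-array multiplicative scale effects, and
additive ln-scale expression shifts planted into chosen gene sets.  Planted
effects are either conserved (active in every species) or species-specific,
and the generator emits a machine-readable ground-truth ledger so recovery
by the analysis pipeline can be scored exactly.

The ln intensity of gene g in sample s is

    ln x[g, s] = b[g] + a[s] + shift(g, group(s)) + e[g, s]

with gene baselines b ~ N(baseline_log_mean, gene_sd^2), array scale
offsets a ~ N(0, array_scale_sd^2) (multiplicative on the raw scale, so
per-array z normalization removes them exactly), planted shifts applied to
member genes of active sets, and residual noise e ~ N(0, noise_sd^2).
Young is the reference group (shift 0); shifts are defined for middle and
old relative to young.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import AGE_GROUPS, ExpressionMatrix, GeneSetCollection

#: (n_young, n_middle, n_old) per species, mirroring the study's cohort.
DEFAULT_GROUP_SIZES: dict[str, tuple[int, int, int]] = {
    "mouse": (5, 5, 5),
    "rat": (5, 5, 5),
    "monkey": (6, 6, 6),
    "human": (5, 4, 7),
}

CONTRASTS = ("middle_vs_young", "old_vs_young")
_CONTRAST_GROUP = {"middle_vs_young": "middle", "old_vs_young": "old"}


@dataclass(frozen=True)
class PlantedEffect:
    """One planted expression shift on the member genes of a gene set.

    ``age_shifts`` gives nonnegative ln-scale magnitudes per non-young age
    group (young is the 0 reference); the sign applied to the data is +1
    for ``direction="up"`` and -1 for ``direction="down"``.
    ``species_scope`` is ``"all"`` (conserved effect) or a tuple of species
    labels (species-specific effect).
    """

    set_name: str
    direction: str  # "up" | "down"
    age_shifts: Mapping[str, float]  # e.g. {"middle": 0.5, "old": 1.0}
    species_scope: str | tuple[str, ...] = "all"

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down"):
            raise ValueError(f"direction must be up/down, got {self.direction!r}")
        shifts = dict(self.age_shifts)
        for grp, mag in shifts.items():
            if grp not in ("middle", "old"):
                raise ValueError(f"age_shifts keys must be middle/old, got {grp!r}")
            if not np.isfinite(mag) or mag < 0:
                raise ValueError(f"shift magnitude for {grp!r} must be finite and >= 0")
        object.__setattr__(self, "age_shifts", shifts)
        if self.species_scope != "all":
            object.__setattr__(self, "species_scope", tuple(self.species_scope))

    def active_in(self, species: str) -> bool:
        return self.species_scope == "all" or species in self.species_scope

    def signed_shift(self, group: str) -> float:
        mag = self.age_shifts.get(group, 0.0)
        return mag if self.direction == "up" else -mag


@dataclass
class SimConfig:
    """Full parameterization of one synthetic cohort.

    Defaults reproduce the study conditions: four species with the cohort's
    group sizes, a 2000-gene universe, and a 60-set C2-style collection.
    """

    species_names: tuple[str, ...] = tuple(DEFAULT_GROUP_SIZES)
    group_sizes: Mapping[str, tuple[int, int, int]] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES)
    )
    n_genes: int = 2000
    n_sets: int = 60
    set_size_range: tuple[int, int] = (15, 40)
    baseline_log_mean: float = 5.0  # ln intensity units (raw ~ e^5 ~ 150)
    gene_sd: float = 1.0  # spread of per-gene baselines, ln scale
    noise_sd: float = 0.3  # residual SD per measurement, ln scale
    array_scale_sd: float = 0.2  # per-array scale offset SD, ln scale
    planted_effects: tuple[PlantedEffect, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        self.species_names = tuple(self.species_names)
        if len(set(self.species_names)) != len(self.species_names):
            raise ValueError("duplicate species names")
        self.group_sizes = {s: tuple(self.group_sizes[s]) for s in self.species_names}
        for s, sizes in self.group_sizes.items():
            if len(sizes) != 3 or any(int(n) < 1 for n in sizes):
                raise ValueError(f"group sizes for {s!r} must be three counts >= 1")
        if self.n_genes < 1 or self.n_sets < 1:
            raise ValueError("n_genes and n_sets must be >= 1")
        lo, hi = self.set_size_range
        if not (1 <= lo <= hi):
            raise ValueError("set_size_range must satisfy 1 <= min <= max")
        if hi > self.n_genes:
            raise ValueError(
                f"set_size_range max {hi} exceeds n_genes {self.n_genes}"
            )
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.gene_sd <= 0:
            raise ValueError("gene_sd must be > 0")
        if self.array_scale_sd < 0:
            raise ValueError("array_scale_sd must be >= 0")
        self.planted_effects = tuple(self.planted_effects)


@dataclass
class GroundTruth:
    """Ledger of planted effects, keyed (species, contrast, set_name).

    Each record holds the planted direction, the signed ln-scale magnitude
    for that contrast's non-reference group, and the member genes actually
    shifted.  Sets/contrasts with zero shift are absent.
    """

    records: dict[str, dict[str, dict[str, dict]]] = field(default_factory=dict)

    def add(
        self,
        species: str,
        contrast: str,
        set_name: str,
        direction: str,
        magnitude: float,
        members: Sequence[str],
    ) -> None:
        self.records.setdefault(species, {}).setdefault(contrast, {})[set_name] = {
            "direction": direction,
            "magnitude": float(magnitude),
            "members": list(members),
        }

    def expected_sets(self, species: str, contrast: str, direction: str) -> set[str]:
        """Planted set names for one (species, contrast, direction)."""
        recs = self.records.get(species, {}).get(contrast, {})
        return {name for name, r in recs.items() if r["direction"] == direction}

    def conserved_sets(
        self, species: Sequence[str], contrast: str, direction: str
    ) -> set[str]:
        """Sets planted in the given direction in every listed species."""
        out: set[str] | None = None
        for sp in species:
            sets = self.expected_sets(sp, contrast, direction)
            out = sets if out is None else out & sets
        return out or set()

    def to_json_dict(self) -> dict:
        return {"records": self.records}

    @classmethod
    def from_json_dict(cls, d: dict) -> "GroundTruth":
        return cls(records=d["records"])


def _species_rng(seed: int, species: str) -> np.random.Generator:
    # Stable per-species stream: adding a species never perturbs the others.
    tag = zlib.crc32(species.encode("utf-8")) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, tag]))


def gene_universe(config: SimConfig) -> list[str]:
    """Ordered gene symbols of the simulated array."""
    width = max(5, len(str(config.n_genes)))
    return [f"GENE_{i:0{width}d}" for i in range(1, config.n_genes + 1)]


def generate_gene_sets(config: SimConfig) -> GeneSetCollection:
    """Draw a C2-style collection of possibly overlapping gene sets.

    Set sizes are uniform on ``set_size_range``; members are sampled
    without replacement from the gene universe, independently per set, so
    overlap between sets occurs at the hypergeometric rate.  Deterministic
    given ``config.seed``.
    """
    universe = np.array(gene_universe(config))
    rng = np.random.default_rng(
        np.random.SeedSequence([int(config.seed) & 0x7FFFFFFF, 0x6E736574])
    )
    lo, hi = config.set_size_range
    sets: dict[str, tuple[str, ...]] = {}
    descriptions: dict[str, str] = {}
    width = max(3, len(str(config.n_sets)))
    for i in range(1, config.n_sets + 1):
        name = f"PATHWAY_{i:0{width}d}"
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(universe, size=size, replace=False)
        sets[name] = tuple(sorted(members))
        descriptions[name] = f"synthetic curated set {i}"
    return GeneSetCollection(sets=sets, descriptions=descriptions, source="synthetic")


def simulate_cohort(
    config: SimConfig, collection: GeneSetCollection | None = None
) -> tuple[dict[str, ExpressionMatrix], GroundTruth]:
    """Generate one expression matrix per species plus the ground truth.

    If ``collection`` is omitted it is regenerated from ``config`` (the
    two calls share the seed, so planted set names always resolve).
    """
    if collection is None:
        collection = generate_gene_sets(config)
    for eff in config.planted_effects:
        if eff.set_name not in collection:
            raise ValueError(f"planted set {eff.set_name!r} not in the collection")
        if eff.species_scope != "all":
            unknown = set(eff.species_scope) - set(config.species_names)
            if unknown:
                raise ValueError(f"planted effect references unknown species {unknown}")

    universe = gene_universe(config)
    index_of = {g: i for i, g in enumerate(universe)}
    truth = GroundTruth()
    matrices: dict[str, ExpressionMatrix] = {}

    for species in config.species_names:
        rng = _species_rng(config.seed, species)
        n_young, n_middle, n_old = config.group_sizes[species]
        groups = (
            ["young"] * n_young + ["middle"] * n_middle + ["old"] * n_old
        )
        n_samples = len(groups)
        sample_ids = []
        counters = {g: 0 for g in AGE_GROUPS}
        for g in groups:
            counters[g] += 1
            sample_ids.append(f"{species}_{g}_{counters[g]}")

        baselines = config.baseline_log_mean + config.gene_sd * rng.standard_normal(
            config.n_genes
        )
        scales = config.array_scale_sd * rng.standard_normal(n_samples)
        noise = config.noise_sd * rng.standard_normal((config.n_genes, n_samples))

        shift = np.zeros((config.n_genes, n_samples))
        for eff in config.planted_effects:
            if not eff.active_in(species):
                continue
            members = collection.members(eff.set_name)
            rows = [index_of[m] for m in members]
            for contrast in CONTRASTS:
                grp = _CONTRAST_GROUP[contrast]
                s = eff.signed_shift(grp)
                if s != 0.0:
                    truth.add(
                        species, contrast, eff.set_name, eff.direction, s, members
                    )
            for j, grp in enumerate(groups):
                s = eff.signed_shift(grp) if grp != "young" else 0.0
                if s != 0.0:
                    shift[rows, j] += s

        ln_values = baselines[:, None] + scales[None, :] + shift + noise
        values = pd.DataFrame(
            np.exp(ln_values), index=universe, columns=sample_ids
        )
        matrices[species] = ExpressionMatrix(
            values=values,
            species=species,
            age_groups=dict(zip(sample_ids, groups)),
        )
    return matrices, truth


def planted_recovery_config(
    seed: int,
    n_conserved_down: int = 2,
    n_species_specific: int = 6,
    old_shift: float = 1.0,
    middle_fraction: float = 0.5,
    **overrides,
) -> SimConfig:
    """Study-shaped recovery scenario: conserved-down plus species-specific sets.

    Plants ``n_conserved_down`` sets downregulated in old age in every
    species (ln shift ``old_shift`` in old, ``middle_fraction`` of it in
    middle age) and ``n_species_specific`` decoy sets, each active in a
    single species with alternating direction.  Set names are assigned from
    the start of the collection so the ground truth is easy to read.
    """
    base = SimConfig(seed=seed, **overrides)
    width = max(3, len(str(base.n_sets)))
    shifts = {"middle": middle_fraction * old_shift, "old": old_shift}
    effects: list[PlantedEffect] = []
    for i in range(n_conserved_down):
        effects.append(
            PlantedEffect(f"PATHWAY_{i + 1:0{width}d}", "down", shifts, "all")
        )
    for j in range(n_species_specific):
        sp = base.species_names[j % len(base.species_names)]
        direction = "up" if j % 2 == 0 else "down"
        effects.append(
            PlantedEffect(
                f"PATHWAY_{n_conserved_down + j + 1:0{width}d}",
                direction,
                shifts,
                (sp,),
            )
        )
    if len(effects) > base.n_sets:
        raise ValueError("more planted effects than sets in the collection")
    return SimConfig(
        seed=seed,
        planted_effects=tuple(effects),
        **overrides,
    )


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    """Serialize the ledger to JSON (lossless round trip)."""
    Path(path).write_text(
        json.dumps(truth.to_json_dict(), indent=2, sort_keys=True) + "\n"
    )


def read_ground_truth(path: str | Path) -> GroundTruth:
    return GroundTruth.from_json_dict(json.loads(Path(path).read_text()))
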