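"""End-to-end orchestration: cohort -> normalization -> contrasts -> PAGE ->
cross-species intersection -> ordination, with reproducible on-disk output.

A run is driven by one :class:`PipelineConfig`, either in simulation mode
(a :class:`~zpage.simulate.SimConfig` embedded in the config) or on real
input files (per-species expression TSVs plus a GMT collection).  All
randomness flows from the single config seed; rerunning an identical
config reproduces byte-identical outputs, recorded as SHA-256 digests in
the run manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io as zio
from . import ordination, page, simulate, xspecies, znorm
from .containers import ExpressionMatrix, GeneSetCollection

logger = logging.getLogger("zpage")

DIRECTIONS = ("up", "down")


@dataclass
class PipelineConfig:
    """Declarative description of one full analysis run."""

    sim: simulate.SimConfig | None = None
    expression_paths: dict[str, str] = field(default_factory=dict)
    gmt_path: str | None = None
    contrasts: tuple[tuple[str, str], ...] = (("middle", "young"), ("old", "young"))
    primary_contrast: tuple[str, str] = ("old", "young")
    z_ratio_min: float = znorm.DEFAULT_Z_RATIO_MIN
    p_max: float = znorm.DEFAULT_P_MAX
    avg_intensity_min: float = znorm.DEFAULT_AVG_INTENSITY_MIN
    p_method: str = "ztest"
    min_set_size: int = page.DEFAULT_MIN_SET_SIZE
    alpha: float = page.DEFAULT_ALPHA
    correction: str = "none"
    require_both_contrasts: bool = False
    pca_components: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        self.contrasts = tuple((a, b) for a, b in self.contrasts)
        self.primary_contrast = tuple(self.primary_contrast)
        if self.primary_contrast not in self.contrasts:
            raise ValueError("primary_contrast must be one of contrasts")
        if self.sim is None and not self.expression_paths:
            raise ValueError("config needs either a sim block or expression_paths")
        if self.sim is None and self.gmt_path is None:
            raise ValueError("non-simulation mode needs a gmt_path")
        # Single-seed policy: in simulation mode the run seed is the only
        # source of randomness, so it overrides the embedded sim seed.
        if self.sim is not None and self.sim.seed != self.seed:
            self.sim = dataclasses.replace(self.sim, seed=self.seed)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        sim = raw.pop("sim", None)
        if sim is not None:
            effects = [
                simulate.PlantedEffect(**e) for e in sim.pop("planted_effects", [])
            ]
            sim = simulate.SimConfig(planted_effects=tuple(effects), **sim)
        return cls(sim=sim, **raw)


def contrast_name(pair: tuple[str, str]) -> str:
    return f"{pair[0]}_vs_{pair[1]}"


@dataclass
class RunResult:
    """In-memory bundle of everything one run computed."""

    matrices: dict[str, ExpressionMatrix]
    zmatrices: dict
    collection: GeneSetCollection
    contrasts: dict[tuple[str, str], znorm.ContrastResult]  # (species, contrast name)
    page_tables: dict[tuple[str, str], page.PathwayScoreTable]
    calls: xspecies.SpeciesPathwayCalls
    venn: dict[str, xspecies.VennReport]  # per direction, primary contrast
    conserved: dict[str, tuple[str, ...]]  # per direction
    pca: dict[tuple[str, str], ordination.PCAResult]  # (species, space)
    ground_truth: simulate.GroundTruth | None = None
    manifest: dict = field(default_factory=dict)


def analyze_cohort(
    matrices: dict[str, ExpressionMatrix],
    collection: GeneSetCollection,
    config: PipelineConfig,
) -> RunResult:
    """Run the full analysis in memory on an already-loaded cohort."""
    zmatrices = {}
    contrasts: dict[tuple[str, str], znorm.ContrastResult] = {}
    tables: dict[tuple[str, str], page.PathwayScoreTable] = {}
    calls = xspecies.SpeciesPathwayCalls(
        thresholds={
            "z_ratio_min": config.z_ratio_min,
            "p_max": config.p_max,
            "avg_intensity_min": config.avg_intensity_min,
            "alpha": config.alpha,
            "correction": config.correction,
            "min_set_size": config.min_set_size,
        }
    )
    pca: dict[tuple[str, str], ordination.PCAResult] = {}
    for species, raw in matrices.items():
        z = znorm.znormalize(raw)
        zmatrices[species] = z
        for pair in config.contrasts:
            cname = contrast_name(pair)
            res = znorm.contrast(
                raw,
                z,
                pair[0],
                pair[1],
                method=config.p_method,
                z_ratio_min=config.z_ratio_min,
                p_max=config.p_max,
                avg_intensity_min=config.avg_intensity_min,
            )
            contrasts[(species, cname)] = res
            table = page.score_sets(
                res.table["z_ratio"],
                collection,
                min_set_size=config.min_set_size,
                species=species,
                contrast=pair,
            )
            tables[(species, cname)] = table
            up, down = page.call_significant_sets(
                table, alpha=config.alpha, correction=config.correction
            )
            calls.add(species, cname, "up", up)
            calls.add(species, cname, "down", down)
            logger.info(
                "%s %s: %d significant genes, %d/%d sets up/down",
                species,
                cname,
                int(res.table["significant"].sum()),
                len(up),
                len(down),
            )
        k = min(
            config.pca_components, len(z.sample_ids) - 1, len(z.gene_symbols)
        )
        pca[(species, "genes")] = ordination.pca_samples(z, k)
        pca[(species, "pathways")] = ordination.pca_pathways(z, collection, k)

    primary = contrast_name(config.primary_contrast)
    venn: dict[str, xspecies.VennReport] = {}
    conserved: dict[str, tuple[str, ...]] = {}
    species_list = list(matrices)
    for direction in DIRECTIONS:
        lists = {sp: calls.get(sp, primary, direction) for sp in species_list}
        if len(species_list) >= 2:
            venn[direction] = xspecies.venn_regions(lists)
        conserved[direction] = xspecies.conserved_pathways(
            calls,
            direction,
            contrast=primary,
            species=species_list,
            require_both_contrasts=config.require_both_contrasts,
        )
        logger.info(
            "conserved %s (%s): %s", direction, primary, list(conserved[direction])
        )
    return RunResult(
        matrices=matrices,
        zmatrices=zmatrices,
        collection=collection,
        contrasts=contrasts,
        page_tables=tables,
        calls=calls,
        venn=venn,
        conserved=conserved,
        pca=pca,
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    if d.get("sim") is not None:
        d["sim"]["planted_effects"] = [
            dataclasses.asdict(e) for e in config.sim.planted_effects
        ]
    return json.loads(json.dumps(d, default=list))


def run_all(config: PipelineConfig, outdir: str | Path) -> RunResult:
    """Execute a configured run and write the result bundle to ``outdir``.

    Layout: per-species subdirectories with ``zmatrix.tsv``,
    ``contrast_<A>_vs_<B>.tsv``, ``page_<contrast>.tsv`` and
    ``pca_<space>.tsv``; pooled ``venn_<direction>.tsv`` and
    ``conserved_<direction>.txt``; ``gene_sets.gmt``; in simulation mode
    ``expression_<species>.tsv`` and ``ground_truth.json``; and a
    ``manifest.json`` recording the seed, thresholds and the SHA-256
    digest of every output file.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    truth = None
    if config.sim is not None:
        logger.info("stage simulate: %d species", len(config.sim.species_names))
        try:
            collection = simulate.generate_gene_sets(config.sim)
            matrices, truth = simulate.simulate_cohort(config.sim, collection)
        except Exception as e:
            raise RuntimeError(f"[simulate] {e}") from e
    else:
        logger.info("stage load: %d matrices", len(config.expression_paths))
        try:
            collection = zio.read_gmt(config.gmt_path)
            matrices = {
                sp: zio.read_expression_tsv(p)
                for sp, p in config.expression_paths.items()
            }
        except Exception as e:
            raise RuntimeError(f"[load] {e}") from e

    try:
        result = analyze_cohort(matrices, collection, config)
    except Exception as e:
        raise RuntimeError(f"[analyze] {e}") from e
    result.ground_truth = truth

    try:
        zio.write_gmt(collection, outdir / "gene_sets.gmt")
        if truth is not None:
            simulate.write_ground_truth(truth, outdir / "ground_truth.json")
            for sp, m in matrices.items():
                zio.write_expression_tsv(m, outdir / f"expression_{sp}.tsv")
        for sp in matrices:
            spdir = outdir / sp
            spdir.mkdir(exist_ok=True)
            zio.write_zscore_tsv(result.zmatrices[sp], spdir / "zmatrix.tsv")
            for pair in config.contrasts:
                cname = contrast_name(pair)
                result.contrasts[(sp, cname)].table.to_csv(
                    spdir / f"contrast_{cname}.tsv",
                    sep="\t",
                    index_label="gene_symbol",
                    float_format=zio.FLOAT_FORMAT,
                )
                result.page_tables[(sp, cname)].table.to_csv(
                    spdir / f"page_{cname}.tsv",
                    sep="\t",
                    index_label="set",
                    float_format=zio.FLOAT_FORMAT,
                )
            for space in ("genes", "pathways"):
                res = result.pca[(sp, space)]
                frame = res.coordinates.copy()
                frame["age_group"] = [
                    result.zmatrices[sp].age_groups[s] for s in frame.index
                ]
                frame.to_csv(
                    spdir / f"pca_{space}.tsv",
                    sep="\t",
                    index_label="sample_id",
                    float_format=zio.FLOAT_FORMAT,
                )
        for direction in DIRECTIONS:
            if direction in result.venn:
                result.venn[direction].to_frame().to_csv(
                    outdir / f"venn_{direction}.tsv", sep="\t", index=False
                )
            (outdir / f"conserved_{direction}.txt").write_text(
                "\n".join(result.conserved[direction])
                + ("\n" if result.conserved[direction] else "")
            )
    except Exception as e:
        raise RuntimeError(f"[write] {e}") from e

    files = sorted(
        p for p in outdir.rglob("*") if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "seed": config.seed,
        "config": _config_dict(config),
        "outputs": {str(p.relative_to(outdir)): _sha256(p) for p in files},
        "n_species": len(matrices),
        "conserved": {d: list(result.conserved[d]) for d in DIRECTIONS},
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    result.manifest = manifest
    return result
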