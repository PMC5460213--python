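"""Readers and writers for the pipeline's plain-text formats.

Expression matrices travel as TSV (first column header ``gene_symbol``,
remaining columns sample IDs) with a sidecar TSV mapping sample ID to
species and age group.  Gene-set collections use standard GMT (set name,
description, tab-separated member symbols).  Ground truth and run
manifests are JSON.  All writers produce canonical, byte-reproducible
output (fixed float format, fixed ordering).
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import pandas as pd

from .containers import ExpressionMatrix, GeneSetCollection, ZScoreMatrix

logger = logging.getLogger("zpage")

FLOAT_FORMAT = "%.10g"


def sidecar_path(path: str | Path) -> Path:
    """Conventional location of the sample-annotation sidecar for a matrix TSV."""
    p = Path(path)
    return p.with_name(p.stem + ".samples.tsv")


def read_expression_tsv(
    path: str | Path, sidecar: str | Path | None = None
) -> ExpressionMatrix:
    """Read a validated expression matrix plus its sample sidecar.

    Errors name the offending coordinates: duplicate case-folded symbols,
    nonnumeric cells, nonpositive intensities and missing sample labels
    are all rejected.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.columns[0] != "gene_symbol":
        raise ValueError(
            f"{path}: first column header must be 'gene_symbol', got {df.columns[0]!r}"
        )
    df = df.set_index("gene_symbol")
    for col in df.columns:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError):
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()].index[0]
            raise ValueError(
                f"{path}: nonnumeric cell at gene {bad!r}, sample {col!r}"
            ) from None
    sidecar = sidecar_path(path) if sidecar is None else Path(sidecar)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing sample sidecar {sidecar}")
    ann = pd.read_csv(sidecar, sep="\t", dtype=str)
    required = {"sample_id", "species", "age_group"}
    if not required <= set(ann.columns):
        raise ValueError(f"{sidecar}: needs columns {sorted(required)}")
    ann = ann.set_index("sample_id")
    missing = [s for s in df.columns if s not in ann.index]
    if missing:
        raise ValueError(f"{sidecar}: no annotation for samples {missing}")
    species = ann.loc[list(df.columns), "species"].unique()
    if len(species) != 1:
        raise ValueError(f"{path}: matrix mixes species {sorted(species)}")
    return ExpressionMatrix(
        values=df,
        species=str(species[0]),
        age_groups=ann.loc[list(df.columns), "age_group"].to_dict(),
    )


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write matrix + sidecar in canonical form (read/write round-trips)."""
    path = Path(path)
    matrix.values.to_csv(
        path, sep="\t", index_label="gene_symbol", float_format=FLOAT_FORMAT
    )
    ann = pd.DataFrame(
        {
            "sample_id": list(matrix.values.columns),
            "species": matrix.species,
            "age_group": [matrix.age_groups[s] for s in matrix.values.columns],
        }
    )
    ann.to_csv(sidecar_path(path), sep="\t", index=False)


def write_zscore_tsv(z: ZScoreMatrix, path: str | Path) -> None:
    z.values.to_csv(
        path, sep="\t", index_label="gene_symbol", float_format=FLOAT_FORMAT
    )


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT gene-set collection.

    Duplicate members within a set are deduplicated with a warning; a line
    with fewer than three fields is an error.
    """
    path = Path(path)
    sets: dict[str, tuple[str, ...]] = {}
    descriptions: dict[str, str] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(
                f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields "
                f"(name, description, members), got {len(fields)}"
            )
        name, desc, *members = fields
        members = [m for m in members if m]
        if name in sets:
            raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
        if len(set(m.upper() for m in members)) != len(members):
            warnings.warn(
                f"{path}:{lineno}: set {name!r} lists duplicate members; deduplicated",
                stacklevel=2,
            )
        sets[name] = tuple(members)
        descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions, source=str(path))


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    lines = []
    for name in collection.names:
        desc = collection.descriptions.get(name, "")
        lines.append("\t".join([name, desc, *collection.members(name)]))
    Path(path).write_text("\n".join(lines) + "\n")
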