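"""Per-array Z normalization, Z-ratio differential statistic, and gene filter.

Each array (sample column) is standardized over its own genes on the
natural-log scale:

    z = (ln x - mean_genes(ln x)) / sd_genes(ln x)

which removes any per-array multiplicative scale factor exactly and makes
arrays from different platforms comparable without a global scaling model.

The differential statistic between age groups A and B (B the reference) is
the Z-ratio: per gene, the difference of group-mean z-scores, standardized
by the standard deviation of those differences taken across all genes of
the contrast,

    d_g = mean_z_A(g) - mean_z_B(g),     Zratio_g = d_g / sd_genes(d).

Sample SD (denominator n-1) is used everywhere.  A gene is called
significantly changed when |Z-ratio| > 1.5, p < 0.05 and average raw
intensity > 0 (all inequalities strict); the thresholds are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix, ZScoreMatrix, normalize_symbol

DEFAULT_Z_RATIO_MIN = 1.5
DEFAULT_P_MAX = 0.05
DEFAULT_AVG_INTENSITY_MIN = 0.0

P_VALUE_METHODS = ("ztest", "t-test")


def znormalize(matrix: ExpressionMatrix) -> ZScoreMatrix:
    """Z-score each array over its own genes on the ln scale.

    Raises if any intensity is nonpositive (the container already enforces
    this) or if an array is constant (zero ln-scale SD).
    """
    if matrix.values.shape[0] < 2:
        raise ValueError("need at least 2 genes per array to z-normalize")
    ln = np.log(matrix.values.to_numpy(dtype=float))
    means = ln.mean(axis=0)
    sds = ln.std(axis=0, ddof=1)
    degenerate = np.flatnonzero(sds == 0)
    if degenerate.size:
        raise ValueError(
            "constant array (zero ln-scale SD): "
            + ", ".join(matrix.values.columns[degenerate])
        )
    z = (ln - means) / sds
    return ZScoreMatrix(
        values=pd.DataFrame(z, index=matrix.values.index, columns=matrix.values.columns),
        species=matrix.species,
        age_groups=dict(matrix.age_groups),
        array_means=pd.Series(means, index=matrix.values.columns),
        array_sds=pd.Series(sds, index=matrix.values.columns),
    )


def collapse_duplicate_symbols(z_values: pd.DataFrame) -> pd.DataFrame:
    """Collapse probe-level rows to one row per case-folded gene symbol.

    Operates on an already z-normalized probe x sample frame whose index may
    contain duplicate symbols (multiple probes per gene); rows sharing a
    symbol are averaged.  Row order follows first appearance.
    """
    canon = pd.Index([normalize_symbol(s) for s in z_values.index], name="gene_symbol")
    out = z_values.groupby(canon, sort=False).mean()
    return out


def _group_columns(z: ZScoreMatrix, group: str | list[str]) -> list[str]:
    if isinstance(group, str):
        return z.samples_in_group(group)
    cols = list(group)
    missing = [c for c in cols if c not in z.values.columns]
    if missing:
        raise ValueError(f"unknown samples: {missing}")
    return cols


def z_ratio(
    z: ZScoreMatrix, group_a: str | list[str], group_b: str | list[str]
) -> pd.Series:
    """Per-gene Z-ratio for group A vs reference group B.

    Groups may be age-group names or explicit sample lists; they must be
    nonempty and disjoint.  Antisymmetric under swapping A and B.
    """
    cols_a = _group_columns(z, group_a)
    cols_b = _group_columns(z, group_b)
    if not cols_a or not cols_b:
        raise ValueError("both groups must be nonempty")
    if set(cols_a) & set(cols_b):
        raise ValueError("groups must be disjoint")
    d = z.values[cols_a].mean(axis=1) - z.values[cols_b].mean(axis=1)
    sd = d.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError(
            "degenerate contrast: zero spread of per-gene group-mean differences"
        )
    return d / sd


def gene_p_values(
    z: ZScoreMatrix,
    group_a: str | list[str],
    group_b: str | list[str],
    method: str = "ztest",
) -> pd.Series:
    """Two-sided per-gene p-values for the A-vs-B contrast.

    ``"ztest"`` (default) treats the Z-ratio as standard normal:
    p = 2 (1 - Phi(|Zratio|)).  ``"t-test"`` runs a per-gene Welch test on
    the z-scores; genes with identical values in both groups get p = 1.
    """
    if method not in P_VALUE_METHODS:
        raise ValueError(f"unknown p-value method {method!r}; use one of {P_VALUE_METHODS}")
    cols_a = _group_columns(z, group_a)
    cols_b = _group_columns(z, group_b)
    if method == "ztest":
        zr = z_ratio(z, cols_a, cols_b)
        return pd.Series(2.0 * stats.norm.sf(np.abs(zr)), index=zr.index)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("t-test requires at least 2 samples per group")
    a = z.values[cols_a].to_numpy()
    b = z.values[cols_b].to_numpy()
    res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    # Welch is 0/0 for zero-variance genes: no difference -> p = 1,
    # an exact repeated difference -> p = 0.
    nan = np.isnan(p)
    if nan.any():
        equal_means = np.isclose(a.mean(axis=1), b.mean(axis=1))
        p[nan & equal_means] = 1.0
        p[nan & ~equal_means] = 0.0
    return pd.Series(p, index=z.values.index)


@dataclass
class ContrastResult:
    """Per-gene differential-expression table for one (species, contrast).

    ``table`` columns: mean_zA, mean_zB, z_ratio, p_value, avg_intensity,
    significant, direction ("up"/"down" for significant genes, "" otherwise).
    """

    species: str
    contrast: tuple[str, str]  # (A, B) with B the reference
    table: pd.DataFrame
    thresholds: dict = field(default_factory=dict)

    @property
    def significant_genes(self) -> pd.Index:
        return self.table.index[self.table["significant"]]

    def significant_in_direction(self, direction: str) -> pd.Index:
        mask = self.table["significant"] & (self.table["direction"] == direction)
        return self.table.index[mask]


def significance_filter(
    result: ContrastResult,
    z_ratio_min: float = DEFAULT_Z_RATIO_MIN,
    p_max: float = DEFAULT_P_MAX,
    avg_intensity_min: float = DEFAULT_AVG_INTENSITY_MIN,
) -> ContrastResult:
    """Apply the three-part gene filter (strict inequalities) in place.

    significant iff |z_ratio| > z_ratio_min and p < p_max and
    avg_intensity > avg_intensity_min; direction is the sign of the
    Z-ratio for significant genes.
    """
    t = result.table
    sig = (
        (t["z_ratio"].abs() > z_ratio_min)
        & (t["p_value"] < p_max)
        & (t["avg_intensity"] > avg_intensity_min)
    )
    t["significant"] = sig
    t["direction"] = np.where(
        sig, np.where(t["z_ratio"] > 0, "up", "down"), ""
    )
    result.thresholds = {
        "z_ratio_min": z_ratio_min,
        "p_max": p_max,
        "avg_intensity_min": avg_intensity_min,
    }
    return result


def contrast(
    raw: ExpressionMatrix,
    z: ZScoreMatrix,
    group_a: str,
    group_b: str,
    method: str = "ztest",
    z_ratio_min: float = DEFAULT_Z_RATIO_MIN,
    p_max: float = DEFAULT_P_MAX,
    avg_intensity_min: float = DEFAULT_AVG_INTENSITY_MIN,
) -> ContrastResult:
    """Full per-gene contrast: Z-ratios, p-values, raw average intensity, flags.

    ``avg_intensity`` is the mean raw intensity over all samples of both
    groups (raw scale, not ln).
    """
    cols_a = z.samples_in_group(group_a)
    cols_b = z.samples_in_group(group_b)
    zr = z_ratio(z, cols_a, cols_b)
    p = gene_p_values(z, cols_a, cols_b, method=method)
    avg = raw.values[cols_a + cols_b].mean(axis=1)
    table = pd.DataFrame(
        {
            "mean_zA": z.values[cols_a].mean(axis=1),
            "mean_zB": z.values[cols_b].mean(axis=1),
            "z_ratio": zr,
            "p_value": p,
            "avg_intensity": avg,
        }
    )
    result = ContrastResult(
        species=raw.species, contrast=(group_a, group_b), table=table
    )
    return significance_filter(result, z_ratio_min, p_max, avg_intensity_min)
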