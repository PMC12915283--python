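"""Brain-wide c-Fos activation and co-activation statistics.

Works on a long-format region table with one row per animal x region
(columns ``animal_id, group, dyad_id, region_acronym, count, volume_mm3``).
Activation is quantified as density (cells per mm^3 of region volume);
regions are screened for differential activation between groups with a
two-sided Mann-Whitney U test at alpha = 0.05 per region, deliberately
without multiple-comparison correction (small-sample exploratory screen);
interregional co-activation is the Pearson correlation of regional
densities across the animals of one group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import InputError
from .stats import mann_whitney_exact

REQUIRED_COLUMNS = ("animal_id", "group", "region_acronym", "count", "volume_mm3")


def _check_table(table: pd.DataFrame):
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise InputError(f"region table missing column(s) {missing}")


def compute_density(table: pd.DataFrame) -> pd.DataFrame:
    """Add a ``density`` column (count / volume); counts and volumes untouched."""
    _check_table(table)
    bad = table.loc[~(table["volume_mm3"] > 0), "region_acronym"].unique()
    if bad.size:
        raise InputError(f"zero or missing volume for region(s) {bad.tolist()}")
    out = table.copy()
    out["density"] = out["count"] / out["volume_mm3"]
    return out


def density_matrix(table: pd.DataFrame, group: str) -> pd.DataFrame:
    """Animals x regions density matrix for one group."""
    sub = table[table["group"] == group]
    if sub.empty:
        raise InputError(f"no animals in group {group!r}")
    return sub.pivot(index="animal_id", columns="region_acronym", values="density")


@dataclass
class ActivationScreenResult:
    """Per-region differential-activation screen between two groups."""

    table: pd.DataFrame  # region, median_a, median_b, U, p, significant, direction
    group_a: str
    group_b: str
    alpha: float

    @property
    def significant_regions(self) -> set:
        return set(self.table.loc[self.table["significant"], "region_acronym"])

    def increased_regions(self) -> set:
        """Regions significantly *increased* in group_a relative to group_b."""
        sig = self.table["significant"] & (self.table["direction"] > 0)
        return set(self.table.loc[sig, "region_acronym"])


def differential_activation(
    table: pd.DataFrame, group_a: str, group_b: str, alpha: float = 0.05
) -> ActivationScreenResult:
    """Per-region two-sided Mann-Whitney screen of ``group_a`` vs ``group_b``.

    Flags p < alpha with no multiple-comparison adjustment; ``direction``
    is the sign of the median density difference (a - b).
    """
    if "density" not in table.columns:
        table = compute_density(table)
    mat_a = density_matrix(table, group_a)
    mat_b = density_matrix(table, group_b)
    if set(mat_a.columns) != set(mat_b.columns):
        raise InputError("groups cover different region sets")
    if len(mat_a) < 3 or len(mat_b) < 3:
        raise InputError("each group needs >= 3 animals")
    rows = []
    for region in mat_a.columns:
        a = mat_a[region].to_numpy()
        b = mat_b[region].to_numpy()
        res = mann_whitney_exact(a, b)
        med_a, med_b = float(np.median(a)), float(np.median(b))
        rows.append(
            {
                "region_acronym": region,
                f"median_{group_a}": med_a,
                f"median_{group_b}": med_b,
                "U": res.statistic,
                "p": res.p,
                "significant": res.p < alpha,
                "direction": float(np.sign(med_a - med_b)),
            }
        )
    return ActivationScreenResult(pd.DataFrame(rows), group_a, group_b, alpha)


@dataclass
class CoactivationMatrix:
    """Region x region Pearson correlation of densities across one group's animals."""

    matrix: pd.DataFrame
    group: str
    n_animals: int
    missing_regions: list  # zero-variance regions with undefined correlations

    def upper_triangle(self) -> np.ndarray:
        """Off-diagonal upper-triangle correlations, defined entries only."""
        m = self.matrix.to_numpy()
        vals = m[np.triu_indices_from(m, k=1)]
        return vals[~np.isnan(vals)]


def coactivation_matrix(table: pd.DataFrame, group: str) -> CoactivationMatrix:
    """Cross-subject Pearson co-activation matrix for one group.

    Symmetric with unit diagonal; correlations involving a zero-variance
    region are recorded as missing (NaN), never silently zero.
    """
    if "density" not in table.columns:
        table = compute_density(table)
    mat = density_matrix(table, group)
    if len(mat) < 3:
        raise InputError("co-activation needs >= 3 animals")
    if mat.shape[1] < 2:
        raise InputError("co-activation needs >= 2 regions")
    x = mat.to_numpy()
    sd = x.std(axis=0)
    missing = [r for r, s in zip(mat.columns, sd) if s == 0]
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(x, rowvar=False)
    corr[sd == 0, :] = np.nan
    corr[:, sd == 0] = np.nan
    np.fill_diagonal(corr, 1.0)
    return CoactivationMatrix(
        matrix=pd.DataFrame(corr, index=mat.columns, columns=mat.columns),
        group=group,
        n_animals=len(mat),
        missing_regions=missing,
    )


@dataclass
class CoactivationComparison:
    """Kruskal-Wallis comparison of co-activation distributions across groups."""

    statistic: float
    p: float
    medians: dict
    n_values: dict
    n_missing: dict


def compare_coactivation(matrices: dict[str, CoactivationMatrix]) -> CoactivationComparison:
    """Compare the upper-triangle correlation distributions of >= 2 groups.

    Missing (zero-variance) correlations are excluded and counted.
    """
    if len(matrices) < 2:
        raise InputError("need >= 2 co-activation matrices")
    region_sets = {frozenset(m.matrix.columns) for m in matrices.values()}
    if len(region_sets) != 1:
        raise InputError("co-activation matrices cover different region sets")
    values = {g: m.upper_triangle() for g, m in matrices.items()}
    n_regions = len(next(iter(matrices.values())).matrix)
    total = n_regions * (n_regions - 1) // 2
    stat, p = sps.kruskal(*values.values())
    return CoactivationComparison(
        statistic=float(stat),
        p=float(p),
        medians={g: float(np.median(v)) for g, v in values.items()},
        n_values={g: int(v.size) for g, v in values.items()},
        n_missing={g: total - int(v.size) for g, v in values.items()},
    )


def apply_region_blacklist(table: pd.DataFrame, excluded) -> pd.DataFrame:
    """Drop rows whose region is in the exclusion list (e.g. hindbrain areas
    prone to registration artifacts)."""
    excluded = set(excluded)
    return table[~table["region_acronym"].isin(excluded)].copy()
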