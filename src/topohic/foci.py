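"""Statistics on fluorescent-foci coordinate tables.

The input is a per-cell table of tagged-locus positions (2-D image
coordinates in micrometres plus a normalized cell-axis coordinate), the
kind of table a spot-detection pipeline exports.  Segmentation itself is
out of scope.  Cells carry at most two foci per tag; cells exceeding that
are excluded from the affected analysis with a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("cell_id", "tag", "x_um", "y_um")


def validate_foci_table(table: pd.DataFrame, max_foci_per_tag: int = 2) -> pd.DataFrame:
    """Check required columns and drop cells with too many foci for a tag."""
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"foci table missing column(s) {missing}")
    if not np.isfinite(table[["x_um", "y_um"]].to_numpy()).all():
        raise ValueError("foci coordinates must be finite")
    counts = table.groupby(["cell_id", "tag"]).size()
    bad = counts[counts > max_foci_per_tag]
    if len(bad):
        bad_cells = bad.index.get_level_values("cell_id").unique()
        logger.warning("excluding %d cell(s) with > %d foci per tag",
                       len(bad_cells), max_foci_per_tag)
        table = table[~table["cell_id"].isin(bad_cells)]
    return table


@dataclass
class DistanceResult:
    distances: pd.DataFrame      # columns: cell_id, closest, furthest
    n_cells_used: int
    n_cells_skipped: int         # cells missing one of the tags

    @property
    def closest(self) -> np.ndarray:
        return self.distances["closest"].to_numpy()

    @property
    def furthest(self) -> np.ndarray:
        return self.distances["furthest"].to_numpy()


def interfocal_distances(table: pd.DataFrame, tagA: str, tagB: str) -> DistanceResult:
    """Per-cell closest and furthest Euclidean distances between two tags.

    All A x B focus pairs in a cell are enumerated; closest is the minimum
    and furthest the maximum (equal when each tag has a single focus).
    Cells missing either tag are skipped and counted.
    """
    table = validate_foci_table(table)
    present = set(table["tag"].unique())
    for tag in (tagA, tagB):
        if tag not in present:
            raise ValueError(f"tag {tag!r} absent from the table")
    out = []
    skipped = 0
    for cell, grp in table.groupby("cell_id", sort=False):
        a = grp.loc[grp["tag"] == tagA, ["x_um", "y_um"]].to_numpy()
        b = grp.loc[grp["tag"] == tagB, ["x_um", "y_um"]].to_numpy()
        if len(a) == 0 or len(b) == 0:
            skipped += 1
            continue
        d = np.hypot(a[:, None, 0] - b[None, :, 0], a[:, None, 1] - b[None, :, 1])
        out.append((cell, float(d.min()), float(d.max())))
    if not out:
        raise ValueError(f"no cell carries both {tagA!r} and {tagB!r}")
    df = pd.DataFrame(out, columns=["cell_id", "closest", "furthest"])
    return DistanceResult(distances=df, n_cells_used=len(df), n_cells_skipped=skipped)


def coloc_fraction(closest, threshold: float = 0.25,
                   conf_level: float = 0.95) -> Tuple[float, Tuple[float, float]]:
    """Fraction of cells whose closest interfocal distance is below the
    colocalization threshold (default 0.25 um = 250 nm), with a binomial
    Wilson confidence interval."""
    closest = np.asarray(closest, dtype=float)
    if closest.size == 0:
        raise ValueError("empty distance sample")
    k = int((closest < threshold).sum())
    n = closest.size
    lo, hi = proportion_confint(k, n, alpha=1 - conf_level, method="wilson")
    return k / n, (float(lo), float(hi))


@dataclass
class FTestResult:
    statistic: float
    p_value: float
    df_num: int
    df_den: int


def variance_f_test(sample_a, sample_b) -> FTestResult:
    """Two-sided F test for equality of variances.

    Convention: the larger unbiased sample variance goes on top, so
    F >= 1; the two-sided p-value is ``2 * min(tail, 1 - tail)`` (capped
    at 1).  Symmetric in its arguments.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 or vb == 0:
        raise ValueError("zero variance in a sample")
    if va >= vb:
        F, dfn, dfd = va / vb, a.size - 1, b.size - 1
    else:
        F, dfn, dfd = vb / va, b.size - 1, a.size - 1
    cdf = sps.f.cdf(F, dfn, dfd)
    p = min(1.0, 2.0 * min(cdf, 1.0 - cdf))
    return FTestResult(statistic=float(F), p_value=float(p), df_num=dfn, df_den=dfd)


def variance_f_tests(table_a: pd.DataFrame, table_b: pd.DataFrame,
                     column: str = "closest",
                     by: Optional[str] = None) -> pd.DataFrame:
    """F tests pooled (``by=None``) or per replicate (``by=<column>``)."""
    if by is None:
        r = variance_f_test(table_a[column], table_b[column])
        return pd.DataFrame([{"group": "pooled", "F": r.statistic, "p": r.p_value,
                              "df_num": r.df_num, "df_den": r.df_den}])
    rows = []
    for grp in sorted(set(table_a[by]) & set(table_b[by])):
        r = variance_f_test(table_a.loc[table_a[by] == grp, column],
                            table_b.loc[table_b[by] == grp, column])
        rows.append({"group": grp, "F": r.statistic, "p": r.p_value,
                     "df_num": r.df_num, "df_den": r.df_den})
    return pd.DataFrame(rows)


def relative_positions(table: pd.DataFrame, tag: str, n_bins: int = 20,
                       polarity: str = "none") -> Tuple[np.ndarray, np.ndarray]:
    """Histogram density of cell-axis coordinates for one tag.

    polarity:
      * ``"none"``   — raw coordinates in [0, 1];
      * ``"fold"``   — coordinates folded about mid-cell (x -> min(x, 1-x)),
        merging the symmetric 1/4 and 3/4 positions;
      * ``"orient"`` — each cell flipped, if needed, so its first focus of
        this tag lies in the first half of the cell.

    Returns ``(density, bin_edges)`` as from ``numpy.histogram``.
    """
    table = validate_foci_table(table)
    if "axial" not in table.columns:
        raise ValueError("foci table has no 'axial' column")
    sub = table[table["tag"] == tag]
    if sub.empty:
        raise ValueError(f"tag {tag!r} absent from the table")
    x = sub["axial"].to_numpy(dtype=float)
    if polarity == "fold":
        x = np.minimum(x, 1.0 - x)
        rng = (0.0, 0.5)
    elif polarity == "orient":
        parts = []
        for _, grp in sub.groupby("cell_id", sort=False):
            xs = grp["axial"].to_numpy(dtype=float)
            parts.append(1.0 - xs if xs[0] > 0.5 else xs)
        x = np.concatenate(parts)
        rng = (0.0, 1.0)
    elif polarity == "none":
        rng = (0.0, 1.0)
    else:
        raise ValueError("polarity must be 'none', 'fold' or 'orient'")
    density, edges = np.histogram(x, bins=n_bins, range=rng, density=True)
    return density, edges
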