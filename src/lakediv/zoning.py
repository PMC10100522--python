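"""Geographic discretization and model design columns.

Lakes are grouped into contiguous elevational and latitudinal zones by an
exact 1-D Fisher-Jenks ("natural breaks") classification, with the zone
count chosen by Sturges' rule.  The same module builds the standardized
predictor and the first/second-order orthogonal polynomial columns used as
fixed effects in the gradient models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "sturges_k",
    "fisher_jenks",
    "fisher_jenks_objective",
    "ZoneAssignment",
    "assign_zones",
    "standardize",
    "DesignColumns",
    "orthogonal_poly",
]


def sturges_k(n: int) -> int:
    """Sturges' rule for the number of classes: ceil(log2 n) + 1.

    For the default study design of 1241 lakes this gives 12 zones.
    """
    if n < 1:
        raise ValueError(f"need at least one observation, got n={n}")
    return int(math.ceil(math.log2(n))) + 1


def fisher_jenks(values, k: int) -> np.ndarray:
    """Exact Fisher-Jenks natural-breaks classification of 1-D data.

    Partitions the sorted values into ``k`` contiguous classes minimising the
    total within-class sum of squared deviations from class means, by exact
    dynamic programming (O(k n^2) with vectorised inner loops).  Ties in the
    objective are broken towards the smallest last-class size.

    Returns the ``k`` ascending class maxima (the last equals max(values)).
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    n_distinct = np.unique(x).size
    if n_distinct < k:
        raise ValueError(
            f"cannot split {n_distinct} distinct values into {k} classes"
        )
    if k < 1:
        raise ValueError("k must be >= 1")

    # prefix sums for O(1) SSE of any contiguous run x[i..j]
    s1 = np.concatenate([[0.0], np.cumsum(x)])
    s2 = np.concatenate([[0.0], np.cumsum(x * x)])

    def seg_cost(i: np.ndarray, j: int) -> np.ndarray:
        # SSE of x[i..j] inclusive, vectorised over start indices i
        cnt = j - i + 1
        tot = s1[j + 1] - s1[i]
        sq = s2[j + 1] - s2[i]
        return sq - tot * tot / cnt

    # dp[c, j] = min cost of splitting x[0..j] into c+1 classes
    dp = np.full((k, n), np.inf)
    cut = np.zeros((k, n), dtype=int)  # start index of last class
    dp[0] = seg_cost(np.zeros(n, dtype=int), np.arange(n))
    for c in range(1, k):
        for j in range(c, n):
            starts = np.arange(c, j + 1)
            cand = dp[c - 1, starts - 1] + seg_cost(starts, j)
            # argmax over reversed candidates -> largest start on ties,
            # i.e. the smallest last class
            best_rev = cand[::-1].argmin()
            best = cand.size - 1 - best_rev
            dp[c, j] = cand[best]
            cut[c, j] = starts[best]
    # recover class maxima
    breaks = np.empty(k)
    j = n - 1
    for c in range(k - 1, -1, -1):
        breaks[c] = x[j]
        j = cut[c, j] - 1
    return breaks


def fisher_jenks_objective(values, breaks) -> float:
    """Total within-class SSE of a right-closed classification by ``breaks``."""
    x = np.sort(np.asarray(values, dtype=float))
    idx = np.searchsorted(np.asarray(breaks)[:-1], x, side="left")
    total = 0.0
    for c in np.unique(idx):
        seg = x[idx == c]
        total += float(np.sum((seg - seg.mean()) ** 2))
    return total


@dataclass
class ZoneAssignment:
    """Per-lake elevational and latitudinal zone labels with break values.

    Zone ids run 1..k in ascending predictor order.  Intervals are closed on
    the right: a lake exactly on a break falls in the lower zone.
    """

    k: int
    elev_breaks: np.ndarray
    lat_breaks: np.ndarray
    table: pd.DataFrame  # columns: lake_id, elev_zone, lat_zone
    width_stats: dict = field(default_factory=dict)

    def zone_of(self, lake_id) -> tuple[int, int]:
        row = self.table.set_index("lake_id").loc[lake_id]
        return int(row["elev_zone"]), int(row["lat_zone"])


def _zone_ids(values: np.ndarray, breaks: np.ndarray) -> np.ndarray:
    # right-closed: value <= break -> lower zone
    return np.searchsorted(breaks[:-1], values, side="left") + 1


def assign_zones(lakes: pd.DataFrame, k: int | None = None) -> ZoneAssignment:
    """Classify lakes into k elevational and k latitudinal zones.

    ``k`` defaults to Sturges' rule on the number of lakes, matching the
    constraint that both axes use the same zone count.
    """
    if k is None:
        k = sturges_k(len(lakes))
    elev = lakes["elevation"].to_numpy(dtype=float)
    lat = lakes["latitude"].to_numpy(dtype=float)
    elev_breaks = fisher_jenks(elev, k)
    lat_breaks = fisher_jenks(lat, k)
    table = pd.DataFrame(
        {
            "lake_id": lakes["lake_id"].to_numpy(),
            "elev_zone": _zone_ids(elev, elev_breaks),
            "lat_zone": _zone_ids(lat, lat_breaks),
        }
    )
    stats = {}
    for name, vals, ids in (
        ("elev", elev, table["elev_zone"]),
        ("lat", lat, table["lat_zone"]),
    ):
        widths = [
            vals[ids == z].max() - vals[ids == z].min()
            for z in range(1, k + 1)
            if np.any(ids == z)
        ]
        stats[f"{name}_zone_widths"] = np.asarray(widths)
        stats[f"{name}_mean_width"] = float(np.mean(widths))
    return ZoneAssignment(
        k=k, elev_breaks=elev_breaks, lat_breaks=lat_breaks, table=table,
        width_stats=stats,
    )


def standardize(x) -> np.ndarray:
    """Center then scale to unit standard deviation (sample sd, ddof=1)."""
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot standardize a constant predictor")
    return (x - x.mean()) / sd


@dataclass
class DesignColumns:
    """Standardized predictor plus unit-norm orthogonal polynomial columns.

    ``poly1``/``poly2`` are mutually orthogonal and orthogonal to the
    intercept, each with unit Euclidean norm.  The stored transform
    (``mean``, ``sd``, ``alpha``, ``beta``, ``norms``) lets the same basis be
    evaluated on new grid points for prediction curves.
    """

    z: np.ndarray
    poly1: np.ndarray
    poly2: np.ndarray
    mean: float
    sd: float
    alpha: float  # projection of z^2 on intercept
    beta: float   # projection of z^2 on poly1
    norms: tuple[float, float]

    def evaluate(self, x_raw) -> tuple[np.ndarray, np.ndarray]:
        """poly1/poly2 values at new raw-predictor points, training basis."""
        z = (np.asarray(x_raw, dtype=float) - self.mean) / self.sd
        p1 = z / self.norms[0]
        p2 = (z * z - self.alpha - self.beta * p1) / self.norms[1]
        return p1, p2


def orthogonal_poly(x_raw, degree: int = 2) -> DesignColumns:
    """First- and second-order orthogonal polynomial design columns.

    The raw predictor is standardized (z-scores), then degree-1 and degree-2
    columns are built by Gram-Schmidt against the intercept and each other.
    Signs are fixed so poly1 correlates positively with the predictor and
    poly2 is positive at the largest |z|.
    """
    if degree != 2:
        raise NotImplementedError("only degree 2 is used in this analysis")
    x_raw = np.asarray(x_raw, dtype=float)
    if np.unique(x_raw).size < 3:
        raise ValueError("need >= 3 distinct predictor values for degree 2")
    n = x_raw.size
    mean, sd = float(x_raw.mean()), float(x_raw.std(ddof=1))
    z = (x_raw - mean) / sd

    zc = z - z.mean()  # exact orthogonality to intercept
    n1 = float(np.linalg.norm(zc))
    p1 = zc / n1

    q = z * z
    alpha = float(q.mean())
    beta = float(q @ p1)
    r = q - alpha - beta * p1
    n2 = float(np.linalg.norm(r))
    if n2 < 1e-12 * n:
        raise ValueError("quadratic column degenerate (predictor too discrete)")
    p2 = r / n2

    if p1 @ z < 0:  # sign conventions; beta rides on p1's sign
        p1, n1, beta = -p1, -n1, -beta
    if p2[np.argmax(np.abs(z))] < 0:
        p2, n2 = -p2, -n2

    return DesignColumns(
        z=z, poly1=p1, poly2=p2, mean=mean, sd=sd,
        alpha=alpha, beta=beta, norms=(n1, n2),
    )
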