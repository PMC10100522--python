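"""Zonal null communities and probit-quantile standardized effect sizes.

Observed functional/phylogenetic metrics are positioned against
richness-matched random communities drawn from a zonal species pool: by
default the union of species observed in lakes sharing BOTH the focal
lake's elevational and latitudinal zone ("cell" scope), widening to the
union of the two zones and then the global pool whenever the cell pool is
smaller than the focal community (the fallback is recorded).

Because null distributions can be asymmetric, the effect size is not the
usual (obs - mean)/sd z-score but the probit of the quantile p-value

    p = (n_below + 0.5 * n_equal + 0.5) / (n_iter + 1),    SES = probit(p),

which is finite by construction (p never reaches 0 or 1), handles ties at
the midpoint, and maps "observed exceeds every null" at 999 iterations to
SES = +3.29.  Positive SES means overdispersion (excess diversity),
negative means clustering, for all four metrics alike.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .diversity import CommunityMetricsEngine
from .zoning import ZoneAssignment

__all__ = ["NullConfig", "SESResult", "null_pool", "null_distribution",
           "probit_ses", "ses_suite", "ses_table"]

SES_METRICS = ("fric", "fdis", "pd", "mpd")


@dataclass
class NullConfig:
    n_iter: int = 999
    pool_scope: str = "cell"  # cell | elev_zone | lat_zone | global
    seed: int = 0
    tie_rule: str = "midpoint"

    def __post_init__(self) -> None:
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if self.pool_scope not in ("cell", "elev_zone", "lat_zone", "global"):
            raise ValueError(f"unknown pool_scope {self.pool_scope!r}")
        if self.tie_rule != "midpoint":
            raise ValueError("only the midpoint tie rule is implemented")


@dataclass
class SESResult:
    observed: float
    null_values: np.ndarray
    p_quantile: float
    ses: float
    reason: str | None = None  # set when SES is missing
    fallback: str | None = None  # pool scope actually used, if widened


def _pool_for_scope(lake_id, zones: ZoneAssignment, occ: pd.DataFrame,
                    scope: str, eligible_taxa: set) -> np.ndarray:
    ztab = zones.table.set_index("lake_id")
    ez, lz = int(ztab.loc[lake_id, "elev_zone"]), int(ztab.loc[lake_id, "lat_zone"])
    if scope == "cell":
        mask = (ztab["elev_zone"] == ez) & (ztab["lat_zone"] == lz)
    elif scope == "elev_zone":
        mask = ztab["elev_zone"] == ez
    elif scope == "lat_zone":
        mask = ztab["lat_zone"] == lz
    elif scope == "zones_union":
        mask = (ztab["elev_zone"] == ez) | (ztab["lat_zone"] == lz)
    elif scope == "global":
        mask = pd.Series(True, index=ztab.index)
    else:
        raise ValueError(f"unknown scope {scope!r}")
    members = ztab.index[mask]
    sub = occ.loc[occ.index.isin(members)]
    present = sub.to_numpy(dtype=bool).any(axis=0)
    taxa = np.asarray(occ.columns)[present]
    return np.array([t for t in taxa if t in eligible_taxa])


def null_pool(lake_id, zones: ZoneAssignment, occ: pd.DataFrame,
              scope: str = "cell", focal_size: int = 0,
              eligible_taxa: set | None = None) -> tuple[np.ndarray, str]:
    """Zonal source pool for a lake's null communities.

    Returns (taxon ids, scope actually used).  When the requested scope
    yields fewer taxa than the focal community, the pool widens along the
    chain cell -> union of the two zones -> global.
    """
    if eligible_taxa is None:
        eligible_taxa = set(occ.columns)
    chain = {
        "cell": ["cell", "zones_union", "global"],
        "elev_zone": ["elev_zone", "global"],
        "lat_zone": ["lat_zone", "global"],
        "global": ["global"],
    }[scope]
    pool = np.array([])
    for sc in chain:
        pool = _pool_for_scope(lake_id, zones, occ, sc, eligible_taxa)
        if pool.size >= focal_size:
            return pool, sc
    if pool.size == 0:
        raise ValueError("empty global pool")
    return pool, "global"


def null_distribution(metric_fn, s: int, pool, cfg: NullConfig,
                      rng: np.random.Generator | None = None) -> np.ndarray:
    """Metric values on ``n_iter`` uniform random S-subsets of the pool."""
    pool = np.asarray(pool)
    if pool.size < s:
        raise ValueError(f"pool of {pool.size} cannot host communities of {s}")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    out = np.empty(cfg.n_iter)
    for i in range(cfg.n_iter):
        out[i] = metric_fn(rng.choice(pool, size=s, replace=False))
    return out


def probit_ses(observed: float, null_values, tie_rule: str = "midpoint") -> SESResult:
    """Probit-transformed quantile p-value of the observed metric."""
    if tie_rule != "midpoint":
        raise ValueError("only the midpoint tie rule is implemented")
    null_values = np.asarray(null_values, dtype=float)
    finite = null_values[np.isfinite(null_values)]
    if observed is None or not np.isfinite(observed):
        return SESResult(np.nan, null_values, np.nan, np.nan, reason="observed missing")
    if finite.size == 0:
        return SESResult(observed, null_values, np.nan, np.nan, reason="no finite nulls")
    close = np.isclose(finite, observed, rtol=1e-12, atol=1e-12)
    n_equal = int(close.sum())
    n_below = int((finite < observed).sum() - (close & (finite < observed)).sum())
    n = finite.size
    p = (n_below + 0.5 * n_equal + 0.5) / (n + 1)
    return SESResult(observed, null_values, p, float(norm.ppf(p)))


def ses_suite(lake_id, occ: pd.DataFrame, taxa: pd.DataFrame,
              engine: CommunityMetricsEngine, zones: ZoneAssignment,
              cfg: NullConfig, rng: np.random.Generator | None = None
              ) -> dict[str, SESResult]:
    """SES for FRic, FDis, PD, MPD at one lake, sharing null draws.

    The four metrics score the same random communities (common random
    numbers), so between-metric SES contrasts are not confounded by draw
    noise.  Communities and pools contain species-level taxa only.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    species_ids = set(taxa.loc[taxa["rank"] == "species", "taxon_id"])
    row = occ.loc[lake_id].to_numpy(dtype=bool)
    present = [t for t, p in zip(occ.columns, row) if p and t in species_ids]
    s = len(present)
    if s < 2:
        return {m: SESResult(np.nan, np.array([]), np.nan, np.nan,
                             reason="community below minimum size")
                for m in SES_METRICS}
    pool, used_scope = null_pool(lake_id, zones, occ, cfg.pool_scope,
                                 focal_size=s, eligible_taxa=species_ids)
    fallback = used_scope if used_scope != cfg.pool_scope else None
    if pool.size < s:
        return {m: SESResult(np.nan, np.array([]), np.nan, np.nan,
                             reason="pool smaller than community after fallbacks")
                for m in SES_METRICS}

    observed = {m: engine.evaluate(m, present) for m in SES_METRICS}
    nulls = {m: np.empty(cfg.n_iter) for m in SES_METRICS}
    for i in range(cfg.n_iter):
        draw = rng.choice(pool, size=s, replace=False)
        for m in SES_METRICS:
            nulls[m][i] = engine.evaluate(m, draw)
    out = {}
    for m in SES_METRICS:
        res = probit_ses(observed[m], nulls[m])
        res.fallback = fallback
        out[m] = res
    return out


def ses_table(occ: pd.DataFrame, taxa: pd.DataFrame,
              engine: CommunityMetricsEngine, zones: ZoneAssignment,
              cfg: NullConfig) -> pd.DataFrame:
    """Per-lake SES columns for all four metrics.

    Each lake gets its own random stream spawned from the config seed and
    the lake's position, so results do not depend on evaluation order.
    """
    root = np.random.SeedSequence(cfg.seed)
    children = root.spawn(len(occ.index))
    rows = []
    for ss, lake_id in zip(children, occ.index):
        rng = np.random.default_rng(ss)
        suite = ses_suite(lake_id, occ, taxa, engine, zones, cfg, rng=rng)
        row = {"lake_id": lake_id}
        for m, res in suite.items():
            row[f"ses_{m}"] = res.ses
            row[f"ses_{m}_p"] = res.p_quantile
            row[f"ses_{m}_reason"] = res.reason
        row["pool_fallback"] = suite["pd"].fallback
        rows.append(row)
    return pd.DataFrame(rows)
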