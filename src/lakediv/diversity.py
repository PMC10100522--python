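"""Per-lake taxonomic, functional, and phylogenetic diversity metrics.

Functional metrics operate in a principal-coordinates (PCoA) embedding of
the Gower dissimilarity matrix over the two measured traits (continuous
body length, ordinal feeding guild treated as interval-scaled with equal
weights).  Functional richness (FRic) is the community convex-hull area as
a fraction of the pool hull; functional dispersion (FDis) the mean distance
of community points to their centroid; community-weighted means (CWM) are
unweighted trait means because the data are incidence only.

Phylogenetic metrics run on the rank-unit taxonomy tree: Faith's PD sums
the branch lengths of the minimal spanning subtree (root path included by
default) and MPD averages patristic distances over all pairs.

Missingness is a value, not an error: lakes below a metric's minimum
community size (or with a degenerate hull) get NaN plus an eligibility
flag, which is why different metrics carry different n downstream.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .io import effective_richness
from .trees import TaxonomyTree

logger = logging.getLogger(__name__)

TRAIT_COLUMNS = ("body_length", "guild")

__all__ = [
    "gower_matrix", "TraitSpace", "build_trait_space", "functional_richness",
    "functional_dispersion", "community_weighted_means", "faith_pd",
    "mean_pairwise_distance", "CommunityMetricsEngine", "community_metrics",
]


# ------------------------------------------------------------------- Gower

def gower_matrix(
    taxa: pd.DataFrame,
    weights: tuple[float, float] = (0.5, 0.5),
    trait_columns: tuple[str, ...] = TRAIT_COLUMNS,
    ordinal_mode: str = "ranked-metric",
) -> pd.DataFrame:
    """Pairwise Gower dissimilarity over the taxon pool.

    d(i,j) = sum_t w_t |x_ti - x_tj| / range_t over traits observed in both
    taxa, renormalised by the weight sum of the observed traits.  The ordinal
    guild enters as interval-scaled ranks (the ranked "metric" treatment).
    Taxa with no observed trait are dropped before computing the matrix.
    """
    if ordinal_mode != "ranked-metric":
        raise NotImplementedError("only the ranked-metric ordinal treatment is provided")
    cols = [c for c in trait_columns if c in taxa.columns]
    if len(cols) != len(trait_columns):
        raise ValueError(f"taxon table lacks trait columns {set(trait_columns) - set(cols)}")
    has_any = taxa[list(trait_columns)].notna().any(axis=1)
    sub = taxa.loc[has_any]
    ids = sub["taxon_id"].to_numpy()
    n = len(sub)
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    for w, col in zip(weights, trait_columns):
        x = sub[col].to_numpy(dtype=float)
        obs = ~np.isnan(x)
        rng_t = np.nanmax(x) - np.nanmin(x) if obs.any() else 0.0
        both = obs[:, None] & obs[None, :]
        if rng_t == 0.0:
            logger.warning(
                "trait %r has zero range over the pool; it contributes 0 "
                "dissimilarity despite weight %.3g", col, w)
            contrib = np.zeros((n, n))
        else:
            diff = np.abs(x[:, None] - x[None, :]) / rng_t
            contrib = np.where(both, diff, 0.0)
        num += w * np.where(both, contrib, 0.0)
        den += w * both
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(den > 0, num / den, np.nan)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=ids, columns=ids)


# -------------------------------------------------------------- trait space

class TraitSpace:
    """PCoA embedding of a dissimilarity matrix with pool hull bookkeeping."""

    def __init__(self, coords: pd.DataFrame, eigenvalues: np.ndarray,
                 correction: str = "none"):
        self.coords = coords            # taxa x retained axes
        self.eigenvalues = eigenvalues  # all axes, descending
        self.correction = correction
        pts = coords.to_numpy()
        try:
            self.pool_hull_volume = float(ConvexHull(pts).volume)
        except QhullError as exc:
            raise ValueError(f"degenerate pool: hull undefined ({exc})") from exc
        if not self.pool_hull_volume > 0:
            raise ValueError("degenerate pool: zero hull volume")
        self._index = {t: i for i, t in enumerate(coords.index)}

    @property
    def n_axes(self) -> int:
        return self.coords.shape[1]

    def points_of(self, taxon_ids) -> np.ndarray:
        idx = [self._index[t] for t in taxon_ids]
        return self.coords.to_numpy()[idx]


def _double_center(d2: np.ndarray) -> np.ndarray:
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * j @ d2 @ j


def _cailliez_constant(d: np.ndarray) -> float:
    # smallest additive constant making the off-diagonal dissimilarities
    # Euclidean: largest real eigenvalue of the 2n x 2n companion matrix
    n = d.shape[0]
    f1 = _double_center(d ** 2)
    f2 = _double_center(d)
    upper = np.hstack([np.zeros((n, n)), 2.0 * f1])
    lower = np.hstack([-np.eye(n), -4.0 * f2])
    eig = np.linalg.eigvals(np.vstack([upper, lower]))
    return float(np.max(eig.real))


def build_trait_space(gower: pd.DataFrame, n_axes: int = 2) -> TraitSpace:
    """Principal-coordinates embedding of a Gower matrix.

    Raw axes are kept when all eigenvalues are >= -1e-8; otherwise the
    Cailliez additive correction is applied before re-embedding.  With the
    two-trait Gower matrix the correction is rarely needed.
    """
    d = np.asarray(gower, dtype=float)
    if np.isnan(d).any():
        raise ValueError("dissimilarity matrix contains NaN")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("dissimilarity matrix must be symmetric")
    if np.all(d == 0):
        raise ValueError("degenerate pool: all dissimilarities are zero")
    correction = "none"
    b = _double_center(d ** 2)
    vals, vecs = np.linalg.eigh(b)
    if vals.min() < -1e-8:
        c = _cailliez_constant(d)
        d_c = d + c
        np.fill_diagonal(d_c, 0.0)
        b = _double_center(d_c ** 2)
        vals, vecs = np.linalg.eigh(b)
        correction = f"cailliez(c={c:.6g})"
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = np.clip(vals[:n_axes], 0.0, None)
    coords = vecs[:, :n_axes] * np.sqrt(pos)
    return TraitSpace(
        coords=pd.DataFrame(coords, index=gower.index,
                            columns=[f"axis{i + 1}" for i in range(n_axes)]),
        eigenvalues=vals,
        correction=correction,
    )


# ---------------------------------------------------------- functional metrics

def _hull_volume(points: np.ndarray, n_axes: int) -> float:
    """Hull measure, or NaN when undefined (too few / degenerate points)."""
    pts = np.unique(points, axis=0)
    if pts.shape[0] <= n_axes:
        return np.nan
    try:
        return float(ConvexHull(pts).volume)
    except QhullError:
        return np.nan  # affinely degenerate community


def functional_richness(space: TraitSpace, community) -> float:
    """Community hull volume as a fraction of the pool hull, or NaN."""
    community = list(community)
    if not community:
        return np.nan
    vol = _hull_volume(space.points_of(community), space.n_axes)
    return vol / space.pool_hull_volume if np.isfinite(vol) else np.nan


def functional_dispersion(space: TraitSpace, community) -> float:
    """Mean Euclidean distance of community points to their centroid."""
    community = list(community)
    if len(community) < 2:
        return np.nan
    pts = space.points_of(community)
    return float(np.mean(np.linalg.norm(pts - pts.mean(axis=0), axis=1)))


def community_weighted_means(taxa: pd.DataFrame, community) -> dict:
    """Unweighted trait means over present taxa (incidence data).

    Taxa missing a trait drop out of that trait's mean only; a trait with no
    observed value in the community yields NaN.
    """
    community = list(community)
    out = {}
    sub = taxa.set_index("taxon_id").loc[community] if community else taxa.iloc[:0]
    for col, name in (("body_length", "cwm_length"), ("guild", "cwm_guild")):
        vals = sub[col].dropna() if len(sub) else []
        out[name] = float(np.mean(vals)) if len(vals) else np.nan
    return out


# --------------------------------------------------------- phylogenetic metrics

def faith_pd(tree: TaxonomyTree, community, include_root: bool = True) -> float:
    """Faith's PD: branch-length sum of the minimal spanning subtree.

    Computed by a post-order count traversal: an edge is spanned when its
    subtree holds at least one community tip; when ``include_root`` is false
    the edges holding *all* community tips (the MRCA-to-root path) drop out.
    """
    members = set(community)
    if len(members) < 2:
        raise ValueError("PD needs a community of at least two taxa")
    missing = members - set(tree.tip_labels)
    if missing:
        raise KeyError(f"taxa not in tree: {sorted(missing)}")
    t = tree.tree
    s = len(members)
    counts: dict[int, int] = {}
    total = 0.0
    for node in t.postorder_node_iter():
        if node.is_leaf():
            c = 1 if node.taxon.label in members else 0
        else:
            c = sum(counts[id(ch)] for ch in node.child_nodes())
        counts[id(node)] = c
        if node is t.seed_node or node.edge.length is None:
            continue
        if c >= 1 and (include_root or c < s):
            total += node.edge.length
    return total


def mean_pairwise_distance(tree: TaxonomyTree, community) -> float:
    """Mean patristic distance over all unordered pairs of community tips."""
    members = list(community)
    if len(members) < 2:
        raise ValueError("MPD needs a community of at least two taxa")
    idx = tree.indices_of(members)
    sub = tree.patristic[np.ix_(idx, idx)]
    n = len(idx)
    return float(sub[np.triu_indices(n, k=1)].mean())


# ----------------------------------------------------------- vectorised engine

class CommunityMetricsEngine:
    """Array-indexed metric evaluation for many communities.

    Precomputes the tree ancestry matrix, patristic matrix, and ordination
    coordinates so the null-model loop can score thousands of random
    communities without touching tree or DataFrame structures.  Communities
    are given as arrays of taxon ids; results match the reference functions.
    """

    def __init__(self, space: TraitSpace | None, tree: TaxonomyTree | None):
        self.space = space
        self.tree = tree
        if space is not None:
            self._coords = space.coords.to_numpy()
            self._space_index = dict(space._index)
        if tree is not None:
            self._ancestry = tree.ancestry
            self._lengths = tree.edge_lengths
            self._patristic = tree.patristic
            self._tree_index = dict(tree.tip_index)

    # communities arrive as taxon-id arrays; unknown ids raise KeyError
    def pd(self, community) -> float:
        idx = [self._tree_index[t] for t in community]
        if len(idx) < 2:
            return np.nan
        spanned = self._ancestry[idx].any(axis=0)
        return float(self._lengths[spanned].sum())

    def mpd(self, community) -> float:
        idx = [self._tree_index[t] for t in community]
        if len(idx) < 2:
            return np.nan
        sub = self._patristic[np.ix_(idx, idx)]
        return float(sub[np.triu_indices(len(idx), k=1)].mean())

    def fdis(self, community) -> float:
        idx = [self._space_index[t] for t in community if t in self._space_index]
        if len(idx) < 2:
            return np.nan
        pts = self._coords[idx]
        return float(np.mean(np.linalg.norm(pts - pts.mean(axis=0), axis=1)))

    def fric(self, community) -> float:
        idx = [self._space_index[t] for t in community if t in self._space_index]
        if not idx:
            return np.nan
        vol = _hull_volume(self._coords[idx], self.space.n_axes)
        return vol / self.space.pool_hull_volume if np.isfinite(vol) else np.nan

    METRICS = ("fric", "fdis", "pd", "mpd")

    def evaluate(self, metric: str, community) -> float:
        return getattr(self, metric)(community)


# ------------------------------------------------------------- metrics table

def community_metrics(
    occ: pd.DataFrame,
    taxa: pd.DataFrame,
    space: TraitSpace,
    tree: TaxonomyTree,
) -> pd.DataFrame:
    """Assemble the per-lake metrics table.

    Species richness applies the juvenile counting rule over all taxa; the
    functional and phylogenetic metrics use species-level taxa only (the
    tree's tips), mirroring how coarse records enter richness but not the
    trait or phylogeny analyses.
    """
    richness = effective_richness(occ, taxa)
    engine = CommunityMetricsEngine(space, tree)
    taxa_idx = taxa.set_index("taxon_id")
    is_species = taxa_idx["rank"] == "species"

    cols = np.asarray(occ.columns)
    mat = occ.to_numpy(dtype=bool)
    species_mask = np.array([bool(is_species.get(c, False)) for c in cols])

    rows = []
    for i, lake in enumerate(occ.index):
        present = cols[mat[i]]
        sp_present = cols[mat[i] & species_mask]
        cwm = community_weighted_means(taxa, present)
        fric = engine.fric(sp_present)
        fdis = engine.fdis(sp_present)
        nsp = len(sp_present)
        pd_v = engine.pd(sp_present) if nsp >= 2 else np.nan
        mpd_v = engine.mpd(sp_present) if nsp >= 2 else np.nan
        rows.append({
            "lake_id": lake,
            "richness": int(richness.loc[lake]),
            "n_species_level": nsp,
            "fric": fric,
            "fdis": fdis,
            "cwm_length": cwm["cwm_length"],
            "cwm_guild": cwm["cwm_guild"],
            "pd": pd_v,
            "mpd": mpd_v,
            "pd_eligible": nsp >= 2,
            "fric_eligible": bool(np.isfinite(fric)),
        })
    return pd.DataFrame(rows)
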