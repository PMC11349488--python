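"""Per-plot alpha diversity, community-weighted means and null models.

Six indices per plot:

* species richness — count of species with cover > 0;
* Shannon diversity H = -sum p_i ln p_i (natural log);
* Faith's PD — total branch length of the minimal (unrooted) subtree
  spanning the plot's species; the root path is excluded unless it is
  needed to connect the set (``include_root=True`` forces it in);
* MPD — unweighted mean pairwise patristic distance;
* FRic — convex-hull volume of the plot's species in reduced trait space
  (Gower dissimilarity -> PCoA, at most 4 retained axes; low-richness plots
  fall back to richness-1 axes, minimum 1, where the hull degenerates to a
  coordinate range);
* FDis — abundance-weighted mean distance of species to the plot's
  abundance-weighted trait-space centroid.

Standardized effect sizes for PD and MPD come from a richness-preserving
null model: random species sets of the observed richness drawn uniformly
from the pool, SES = (obs - null mean)/null SD with a two-sided Monte Carlo
p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .traits import phylo_eigenvectors


# --------------------------------------------------------------------------- #
# Taxonomic
# --------------------------------------------------------------------------- #

def richness_shannon(abundances: np.ndarray | pd.Series) -> tuple[int, float]:
    """(richness, Shannon H in nats); an empty plot scores (0, 0)."""
    a = np.asarray(abundances, dtype=float)
    if (a < 0).any():
        raise ValueError("negative abundance")
    present = a[a > 0]
    if present.size == 0:
        return 0, 0.0
    p = present / present.sum()
    return int(present.size), float(-(p * np.log(p)).sum())


# --------------------------------------------------------------------------- #
# Phylogenetic
# --------------------------------------------------------------------------- #

def faith_pd(
    species: list[str] | set[str], tree: dendropy.Tree, include_root: bool = False
) -> float:
    """Faith's phylogenetic diversity of a species set.

    Sum of edge lengths of the minimal subtree connecting the tips; an edge
    is needed iff it separates part of the set from the rest (its subtree
    holds between 1 and S-1 of the S set members). With ``include_root``
    every edge on a path from the set to the root counts as well.
    """
    wanted = set(species)
    tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    missing = wanted - tips
    if missing:
        raise KeyError(f"species not in tree: {sorted(missing)}")
    S = len(wanted)
    if S == 0:
        return 0.0
    total = 0.0
    counts: dict[object, int] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            c = 1 if node.taxon.label in wanted else 0
        else:
            c = sum(counts[ch] for ch in node.child_nodes())
        counts[node] = c
        bl = node.edge.length or 0.0
        if include_root:
            if 1 <= c:
                total += bl if node.parent_node is not None else 0.0
        else:
            if 1 <= c <= S - 1:
                total += bl
    return total


def mpd(species: list[str], dist: pd.DataFrame) -> float:
    """Unweighted mean pairwise patristic distance; NaN below 2 species."""
    sp = list(dict.fromkeys(species))
    if len(sp) < 2:
        return float("nan")
    sub = dist.loc[sp, sp].to_numpy()
    iu = np.triu_indices(len(sp), k=1)
    return float(sub[iu].mean())


# --------------------------------------------------------------------------- #
# Functional
# --------------------------------------------------------------------------- #

def gower_distance(traits: pd.DataFrame) -> pd.DataFrame:
    """Gower dissimilarity over mixed numeric/categorical traits.

    Numeric contributions are |x_i - x_j| / range; categorical contributions
    are 0/1 mismatch; traits weigh equally. Zero-range traits are dropped.
    """
    n = len(traits)
    parts = []
    for col in traits.columns:
        s = traits[col]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            v = s.astype(str).to_numpy()
            parts.append((v[:, None] != v[None, :]).astype(float))
        else:
            v = s.to_numpy(dtype=float)
            rng = np.nanmax(v) - np.nanmin(v)
            if rng == 0:
                continue
            parts.append(np.abs(v[:, None] - v[None, :]) / rng)
    if not parts:
        return pd.DataFrame(np.zeros((n, n)), index=traits.index, columns=traits.index)
    D = np.mean(parts, axis=0)
    return pd.DataFrame(D, index=traits.index, columns=traits.index)


def functional_space(traits: pd.DataFrame, n_axes: int | None = None) -> pd.DataFrame:
    """Species coordinates: Gower dissimilarity -> PCoA, few leading axes.

    Default retains min(4, S-1) positive axes, the convention of
    convex-hull functional richness (hull volume in high dimension needs
    more points than most plots have species).
    """
    D = gower_distance(traits)
    if n_axes is None:
        n_axes = min(4, len(traits) - 1)
    ev = phylo_eigenvectors(D, n_keep=n_axes)
    return ev.vectors


def fric(species: list[str], coords: pd.DataFrame) -> float:
    """Convex-hull volume of the species' coordinates.

    When richness <= the number of axes the hull is degenerate: axes are
    reduced to richness-1 (minimum 1, where FRic is the coordinate range).
    Fewer than 2 species -> NaN.
    """
    sp = list(dict.fromkeys(species))
    if len(sp) < 2:
        return float("nan")
    pts = coords.loc[sp].to_numpy(dtype=float)
    n_axes = min(pts.shape[1], len(sp) - 1)
    pts = pts[:, :n_axes]
    if n_axes == 1:
        return float(pts.max() - pts.min())
    try:
        return float(ConvexHull(pts).volume)
    except QhullError:
        # coplanar/collinear points: retry in successively fewer axes
        for k in range(n_axes - 1, 0, -1):
            if k == 1:
                return float(pts[:, 0].max() - pts[:, 0].min())
            try:
                return float(ConvexHull(pts[:, :k]).volume)
            except QhullError:
                continue
        return float("nan")


def fdis(abundances: pd.Series, coords: pd.DataFrame) -> float:
    """Abundance-weighted mean distance to the weighted centroid."""
    a = abundances[abundances > 0]
    if a.empty:
        return float("nan")
    pts = coords.loc[a.index].to_numpy(dtype=float)
    w = a.to_numpy(dtype=float)
    centroid = (w[:, None] * pts).sum(axis=0) / w.sum()
    d = np.linalg.norm(pts - centroid, axis=1)
    return float((w * d).sum() / w.sum())


def cwm(abundances: pd.Series, trait: pd.Series) -> float:
    """Community-weighted mean of one trait.

    Species without trait data are dropped and weights renormalized over
    the remainder; a plot with no trait coverage scores NaN.
    """
    a = abundances[abundances > 0]
    t = trait.reindex(a.index)
    ok = t.notna()
    if not ok.any():
        return float("nan")
    w = a[ok].to_numpy(dtype=float)
    return float((w * t[ok].to_numpy(dtype=float)).sum() / w.sum())


# --------------------------------------------------------------------------- #
# Null models
# --------------------------------------------------------------------------- #

@dataclass
class NullModelConfig:
    n_randomizations: int = 999
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_randomizations < 1:
            raise ValueError("need >= 1 randomization")


def ses_null(
    metric: str,
    species: list[str],
    pool: list[str],
    tree: dendropy.Tree | None = None,
    dist: pd.DataFrame | None = None,
    config: NullModelConfig | None = None,
) -> tuple[float, float]:
    """Richness-preserving null model SES and two-sided p for PD or MPD.

    Draws ``n_randomizations`` uniform species sets of the observed richness
    from ``pool``; SES = (obs - null mean)/null SD; p = 2 min(r+1, n-r+1)/(n+1)
    with r the count of null values <= observed. Zero null SD yields NaN SES.
    """
    config = config or NullModelConfig()
    if metric == "pd":
        if tree is None:
            raise ValueError("pd needs a tree")
        observe = lambda sp: faith_pd(sp, tree)
    elif metric == "mpd":
        if dist is None:
            raise ValueError("mpd needs a distance matrix")
        observe = lambda sp: mpd(sp, dist)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    S = len(set(species))
    if S == 0 or (metric == "mpd" and S < 2):
        return float("nan"), float("nan")
    rng = np.random.default_rng(config.seed)
    obs = observe(list(species))
    pool_arr = np.asarray(sorted(set(pool)))
    nulls = np.empty(config.n_randomizations)
    for i in range(config.n_randomizations):
        draw = rng.choice(pool_arr, size=S, replace=False)
        nulls[i] = observe(list(draw))
    sd = nulls.std()
    n = config.n_randomizations
    r = int((nulls <= obs).sum())
    p = 2.0 * min(r + 1, n - r + 1) / (n + 1)
    if sd == 0:
        return float("nan"), min(p, 1.0)
    return float((obs - nulls.mean()) / sd), float(min(p, 1.0))


# --------------------------------------------------------------------------- #
# Profile assembly
# --------------------------------------------------------------------------- #

def diversity_profile(
    community: pd.DataFrame,
    tree: dendropy.Tree | None = None,
    dist: pd.DataFrame | None = None,
    coords: pd.DataFrame | None = None,
    traits: pd.DataFrame | None = None,
    null_config: NullModelConfig | None = None,
) -> pd.DataFrame:
    """Per-plot diversity table over a plots x species cover matrix.

    Columns: richness, shannon, and — when the inputs are supplied —
    faith_pd, mpd, fric, fdis, CWM per numeric trait, and SES/p columns for
    the phylogenetic metrics. Metrics undefined for a plot are NaN.
    """
    rows = {}
    pool = list(community.columns)
    for plot, ab in community.iterrows():
        rec: dict[str, float] = {}
        rec["richness"], rec["shannon"] = richness_shannon(ab)
        present = list(ab.index[ab > 0])
        if tree is not None:
            rec["faith_pd"] = faith_pd(present, tree) if present else float("nan")
        if dist is not None:
            rec["mpd"] = mpd(present, dist)
        if coords is not None:
            rec["fric"] = fric(present, coords)
            rec["fdis"] = fdis(ab, coords) if present else float("nan")
        if traits is not None:
            for col in traits.columns:
                if traits[col].dtype != object and not isinstance(
                    traits[col].dtype, pd.CategoricalDtype
                ):
                    rec[f"cwm_{col}"] = cwm(ab, traits[col])
        if null_config is not None and tree is not None and present:
            rec["pd_ses"], rec["pd_p"] = ses_null(
                "pd", present, pool, tree=tree, config=null_config
            )
            if dist is not None:
                rec["mpd_ses"], rec["mpd_p"] = ses_null(
                    "mpd", present, pool, dist=dist, config=null_config
                )
        rows[plot] = rec
    return pd.DataFrame.from_dict(rows, orient="index")
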