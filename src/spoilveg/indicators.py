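"""Indicator species analysis (group-equalized IndVal) and NMDS ordination.

For a species and a combination C of site groups, the group-equalized
specificity is A_C = (sum of the species' per-group mean abundances over
groups in C) / (sum over all groups), the fidelity is B_C = (occupied plots
in C) / (plots in C), and IndVal_C = sqrt(A_C * B_C). Equalizing by group
means removes the bias of unequal group sizes. Each species is assigned the
combination (up to order K-1) maximizing its statistic; significance comes
from permuting the plot-to-group assignment, or from exhaustive enumeration
of all relabelings on small designs.

NMDS embeds Bray-Curtis dissimilarities of presence/absence data (equal to
Sorensen dissimilarity) in two dimensions by minimizing Kruskal stress-1
with iterative majorization (Guttman transform) alternated with monotone
(pool-adjacent-violators) regression, taking the best of several random
starts. Empty and single-species plots are excluded beforehand — they
produce degenerate dissimilarities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, permutations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression


# --------------------------------------------------------------------------- #
# IndVal
# --------------------------------------------------------------------------- #

def _group_stats(
    comm: np.ndarray, group_idx: list[np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-group mean abundance (G, S) and presence counts (G, S)."""
    means = np.stack([comm[idx].mean(axis=0) for idx in group_idx])
    pres = np.stack([(comm[idx] > 0).sum(axis=0) for idx in group_idx])
    return means, pres


def _max_indval(
    comm: np.ndarray,
    group_idx: list[np.ndarray],
    combos: list[tuple[int, ...]],
    mode: str,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-species max IndVal over combos: (stat, A, B, combo index)."""
    means, pres = _group_stats(comm, group_idx)
    if mode == "presence":
        sizes = np.array([idx.size for idx in group_idx])[:, None]
        means = pres / sizes
    total_mean = means.sum(axis=0)
    n_species = comm.shape[1]
    best = np.zeros(n_species)
    bestA = np.zeros(n_species)
    bestB = np.zeros(n_species)
    best_combo = np.zeros(n_species, dtype=int)
    for ci, combo in enumerate(combos):
        idx = list(combo)
        with np.errstate(invalid="ignore", divide="ignore"):
            A = np.where(total_mean > 0, means[idx].sum(axis=0) / total_mean, 0.0)
        n_plots = sum(group_idx[g].size for g in idx)
        B = pres[idx].sum(axis=0) / n_plots
        stat = np.sqrt(A * B)
        better = stat > best + 1e-15
        best[better] = stat[better]
        bestA[better], bestB[better] = A[better], B[better]
        best_combo[better] = ci
    return best, bestA, bestB, best_combo


def indval(
    community: pd.DataFrame,
    groups: pd.Series,
    mode: str = "abundance",
    max_order: int | None = None,
) -> pd.DataFrame:
    """Group-equalized IndVal per species over group combinations.

    Returns a frame indexed by species with columns ``stat``, ``A``, ``B``
    and ``groups`` (the maximizing combination as a tuple of group labels).
    ``mode`` uses cover abundances (default) or presence frequencies.
    """
    groups = groups.reindex(community.index)
    if groups.isna().any():
        raise ValueError("every plot needs a group")
    labels = [g.item() if isinstance(g, np.generic) else g
              for g in sorted(groups.unique())]
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    for g in labels:
        if (groups == g).sum() == 0:
            raise ValueError(f"empty group {g}")
    if max_order is None:
        max_order = len(labels) - 1
    comm = community.to_numpy(dtype=float)
    group_idx = [np.flatnonzero((groups == g).to_numpy()) for g in labels]
    combos = [c for r in range(1, max_order + 1) for c in combinations(range(len(labels)), r)]
    stat, A, B, which = _max_indval(comm, group_idx, combos, mode)
    return pd.DataFrame(
        {
            "stat": stat, "A": A, "B": B,
            "groups": [tuple(labels[g] for g in combos[w]) for w in which],
        },
        index=community.columns,
    )


def indval_permutation_p(
    community: pd.DataFrame,
    groups: pd.Series,
    n_perm: int = 999,
    seed: int = 0,
    mode: str = "abundance",
    max_order: int | None = None,
    exhaustive: bool = False,
) -> pd.DataFrame:
    """IndVal with permutation p-values.

    Random mode permutes the plot-to-group assignment ``n_perm`` times and
    uses the estimator p = (1 + #{perm stat >= observed}) / (1 + n_perm).
    ``exhaustive`` enumerates every distinct relabeling with the observed
    group sizes (small designs only) and reports the exact proportion.
    """
    base = indval(community, groups, mode=mode, max_order=max_order)
    groups = groups.reindex(community.index)
    labels = sorted(groups.unique())
    if max_order is None:
        max_order = len(labels) - 1
    comm = community.to_numpy(dtype=float)
    combos = [c for r in range(1, max_order + 1) for c in combinations(range(len(labels)), r)]
    obs = base["stat"].to_numpy()
    g_codes = groups.map({g: i for i, g in enumerate(labels)}).to_numpy()

    def stat_for(assign: np.ndarray) -> np.ndarray:
        gi = [np.flatnonzero(assign == i) for i in range(len(labels))]
        return _max_indval(comm, gi, combos, mode)[0]

    if exhaustive:
        seen = set()
        count = np.zeros_like(obs)
        total = 0
        for perm in permutations(g_codes):
            if perm in seen:
                continue
            seen.add(perm)
            total += 1
            count += stat_for(np.array(perm)) >= obs - 1e-12
        p = count / total
    else:
        rng = np.random.default_rng(seed)
        count = np.zeros_like(obs)
        for _ in range(n_perm):
            count += stat_for(rng.permutation(g_codes)) >= obs - 1e-12
        p = (1.0 + count) / (1.0 + n_perm)
    out = base.copy()
    out["p"] = p
    out["n_perm"] = total if exhaustive else n_perm
    return out


# --------------------------------------------------------------------------- #
# Ordination
# --------------------------------------------------------------------------- #

def filter_for_ordination(community: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop empty and single-species plots; returns (subset, exclusion log)."""
    richness = (community > 0).sum(axis=1)
    log = pd.DataFrame({"richness": richness[richness < 2]})
    log["reason"] = np.where(log["richness"] == 0, "empty", "singleton")
    return community.loc[richness >= 2], log


@dataclass
class NmdsResult:
    coordinates: pd.DataFrame
    stress: float
    n_starts: int
    converged: bool
    excluded: pd.DataFrame = field(default_factory=pd.DataFrame)
    stress_history: list[float] = field(default_factory=list)


def _stress1(dhat: np.ndarray, d: np.ndarray) -> float:
    return float(np.sqrt(((d - dhat) ** 2).sum() / (d ** 2).sum()))


def _nmds_single(
    diss: np.ndarray, dims: int, rng: np.random.Generator, max_iter: int, tol: float
) -> tuple[np.ndarray, float, list[float]]:
    n = diss.shape[0]
    iu = np.triu_indices(n, k=1)
    delta = diss[iu]
    order = np.argsort(delta, kind="stable")
    iso = IsotonicRegression(increasing=True)
    X = rng.standard_normal((n, dims))
    history: list[float] = []
    last = np.inf
    for _ in range(max_iter):
        d = pdist(X)
        dhat = np.empty_like(d)
        dhat[order] = iso.fit_transform(np.arange(order.size), d[order])
        stress = _stress1(dhat, d)
        history.append(stress)
        if last - stress < tol:
            break
        last = stress
        # Guttman transform with target distances dhat
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(d > 0, dhat / d, 0.0)
        B = -squareform(ratio)
        np.fill_diagonal(B, -B.sum(axis=1))
        X = B @ X / n
    return X, history[-1] if history else np.inf, history


def nmds(
    community: pd.DataFrame,
    dims: int = 2,
    n_starts: int = 8,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-7,
) -> NmdsResult:
    """Two-dimensional NMDS of presence/absence Bray-Curtis dissimilarities.

    Runs ``n_starts`` random starts of majorization + monotone regression
    and keeps the lowest-stress configuration, centered and rotated to its
    principal axes.
    """
    subset, excluded = filter_for_ordination(community)
    if len(subset) < 3:
        raise ValueError("need >= 3 plots with >= 2 species")
    pa = (subset.to_numpy(dtype=float) > 0).astype(float)
    diss = squareform(pdist(pa, metric="braycurtis"))
    if not diss.any():
        raise ValueError("all plots identical; dissimilarities are zero")
    rng = np.random.default_rng(seed)
    best: tuple[np.ndarray, float, list[float]] | None = None
    for _ in range(n_starts):
        X, stress, history = _nmds_single(diss, dims, rng, max_iter, tol)
        if best is None or stress < best[1]:
            best = (X, stress, history)
    X, stress, history = best
    X = X - X.mean(axis=0)
    _, _, vt = np.linalg.svd(X, full_matrices=False)
    X = X @ vt.T
    coords = pd.DataFrame(
        X, index=subset.index, columns=[f"NMDS{i + 1}" for i in range(dims)]
    )
    return NmdsResult(
        coordinates=coords, stress=stress, n_starts=n_starts,
        converged=len(history) < max_iter, excluded=excluded,
        stress_history=history,
    )
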