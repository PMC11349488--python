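"""Phylogenetic eigenvectors and random-forest trait imputation.

Missing trait values are imputed by the iterative random-forest scheme of
chained missForest-style regression: each trait in turn is modelled on all
other traits plus phylogenetic eigenvectors, missing cells are re-predicted,
and iterations stop when the change in imputed values first increases
(returning the previous iterate). Phylogenetic eigenvectors come from a
principal coordinates analysis (PCoA) of the patristic distance matrix:
double-center -D^2/2 (Gower centering), eigendecompose, and scale each
retained axis by the square root of its eigenvalue, so the eigenvectors
summarize phylogenetic relatedness as orthogonal numeric predictors.

Regression forests use a minimum leaf size of 5 (the classical
random-forest regression default); classification trees grow to purity.

Reported errors follow the missForest conventions: NRMSE =
sqrt(MSE / Var(observed)) pooled over continuous traits computed from
out-of-bag predictions (it can exceed 1 for signal-free traits), and PFC =
out-of-bag misclassification proportion for categorical traits.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor


def patristic_distances(tree: dendropy.Tree) -> pd.DataFrame:
    """Tip-to-tip path-length (patristic) distance matrix."""
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate tip labels")
    # bipartition encoding mutates tree state; work on a clone
    pdm = tree.clone(depth=1).phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace if t.label in set(labels)}
    n = len(labels)
    D = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[a], taxa[labels[j]])
            D[i, j] = D[j, i] = d
    return pd.DataFrame(D, index=labels, columns=labels)


@dataclass
class EigenvectorSet:
    """Retained PCoA axes of the phylogenetic distance matrix."""

    vectors: pd.DataFrame          # species x retained axes, scaled by sqrt(eigenvalue)
    eigenvalues: np.ndarray        # all positive eigenvalues, non-increasing
    cumulative_proportion: float   # variation represented by the retained axes

    @property
    def n_retained(self) -> int:
        return self.vectors.shape[1]


def phylo_eigenvectors(
    D: pd.DataFrame | np.ndarray,
    n_keep: int | None = None,
    variance_target: float | None = None,
) -> EigenvectorSet:
    """Principal coordinates of a distance matrix.

    Retains either the first ``n_keep`` axes or the smallest number of
    leading axes whose cumulative share of the positive eigenvalue mass
    reaches ``variance_target``; by default all positive axes.
    """
    if isinstance(D, pd.DataFrame):
        labels = list(D.index)
        M = D.to_numpy(dtype=float)
    else:
        M = np.asarray(D, dtype=float)
        labels = [f"s{i}" for i in range(M.shape[0])]
    if M.shape[0] != M.shape[1] or not np.allclose(M, M.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    n = M.shape[0]
    A = -0.5 * M ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    G = J @ A @ J
    evals, evecs = np.linalg.eigh(G)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > max(evals.max(), 0) * 1e-10
    evals_pos, evecs_pos = evals[pos], evecs[:, pos]
    total = evals_pos.sum()
    if n_keep is not None:
        keep = min(n_keep, evals_pos.size)
    elif variance_target is not None:
        cum = np.cumsum(evals_pos) / total
        keep = int(np.searchsorted(cum, variance_target) + 1)
        keep = min(keep, evals_pos.size)
    else:
        keep = evals_pos.size
    scores = evecs_pos[:, :keep] * np.sqrt(evals_pos[:keep])
    vectors = pd.DataFrame(
        scores, index=labels, columns=[f"PEV{i + 1}" for i in range(keep)]
    )
    return EigenvectorSet(
        vectors=vectors, eigenvalues=evals_pos,
        cumulative_proportion=float(evals_pos[:keep].sum() / total),
    )


@dataclass
class ImputationReport:
    nrmse: float               # OOB, pooled over continuous traits (NaN if none)
    pfc: float                 # OOB, pooled over categorical traits (NaN if none)
    iterations: int
    converged: bool


def _is_categorical(s: pd.Series) -> bool:
    return isinstance(s.dtype, pd.CategoricalDtype) or s.dtype == object


def impute_missforest(
    observed: pd.DataFrame,
    predictors: EigenvectorSet | pd.DataFrame | None = None,
    n_trees: int = 100,
    max_iter: int = 10,
    seed: int = 0,
) -> tuple[pd.DataFrame, ImputationReport]:
    """Iterative random-forest imputation of a mixed-type trait table.

    Missing numerics start at column means, categoricals at column modes.
    Each iteration visits traits in increasing-missingness order, fits a
    forest of the trait on all other columns (one-hot-encoded categoricals)
    plus any supplied predictors using rows where the trait is observed, and
    re-predicts the missing rows. Iterations stop when the normalized change
    in imputed values first increases; the previous iterate is returned.
    Observed entries are never altered.
    """
    X = observed.copy()
    if predictors is not None:
        P = predictors.vectors if isinstance(predictors, EigenvectorSet) else predictors
        P = P.loc[X.index]
    else:
        P = pd.DataFrame(index=X.index)
    traits = list(X.columns)
    miss = {t: X[t].isna().to_numpy() for t in traits}
    if any(m.all() for m in miss.values()):
        raise ValueError("a trait is entirely missing")
    if len(X) < 2:
        raise ValueError("need at least 2 species")
    cat = {t: _is_categorical(X[t]) for t in traits}
    n_missing = {t: int(m.sum()) for t, m in miss.items()}

    # initial fill: column mean / mode
    filled = X.copy()
    for t in traits:
        if n_missing[t] == 0:
            continue
        if cat[t]:
            filled[t] = filled[t].fillna(X[t].mode(dropna=True).iloc[0])
        else:
            filled[t] = filled[t].fillna(X[t].mean())

    if all(v == 0 for v in n_missing.values()):
        report = _oob_errors(filled, P, traits, cat, n_trees, seed)
        return filled, ImputationReport(report[0], report[1], 0, True)

    order = sorted((t for t in traits if n_missing[t] > 0), key=lambda t: n_missing[t])
    rng = np.random.default_rng(seed)

    def design(frame: pd.DataFrame, exclude: str) -> np.ndarray:
        parts = [P.to_numpy(dtype=float)] if P.shape[1] else []
        for t in traits:
            if t == exclude:
                continue
            col = frame[t]
            if cat[t]:
                parts.append(pd.get_dummies(col).to_numpy(dtype=float))
            else:
                parts.append(col.to_numpy(dtype=float)[:, None])
        return np.hstack(parts) if parts else np.zeros((len(frame), 0))

    prev = filled.copy()
    prev_change = np.inf
    converged = False
    iterations = 0
    for _ in range(max_iter):
        current = prev.copy()
        for t in order:
            y = current[t]
            obs = ~miss[t]
            Xmat = design(current, t)
            rs = int(rng.integers(2**31 - 1))
            if cat[t]:
                model = RandomForestClassifier(n_estimators=n_trees, max_features="sqrt", random_state=rs)
                model.fit(Xmat[obs], y[obs].astype(str))
                pred = model.predict(Xmat[miss[t]])
                current.loc[miss[t], t] = pred
            else:
                model = RandomForestRegressor(n_estimators=n_trees, max_features="sqrt",
                                              min_samples_leaf=5, random_state=rs)
                model.fit(Xmat[obs], y[obs].to_numpy(dtype=float))
                current.loc[miss[t], t] = model.predict(Xmat[miss[t]])
        iterations += 1
        # normalized change in the imputed cells only
        num_sq, num_den, cat_dis, cat_n = 0.0, 0.0, 0, 0
        for t in order:
            m = miss[t]
            if cat[t]:
                cat_dis += int((current.loc[m, t].astype(str) != prev.loc[m, t].astype(str)).sum())
                cat_n += int(m.sum())
            else:
                new = current.loc[m, t].to_numpy(dtype=float)
                old = prev.loc[m, t].to_numpy(dtype=float)
                num_sq += float(((new - old) ** 2).sum())
                num_den += float((new ** 2).sum())
        change = (num_sq / num_den if num_den > 0 else 0.0) + (
            cat_dis / cat_n if cat_n > 0 else 0.0
        )
        if change >= prev_change:
            converged = True
            break               # previous iterate is the answer
        prev, prev_change = current, change

    nrmse, pfc = _oob_errors(prev, P, traits, cat, n_trees, seed)
    return prev, ImputationReport(nrmse, pfc, iterations, converged)


def _oob_errors(
    filled: pd.DataFrame,
    P: pd.DataFrame,
    traits: list[str],
    cat: dict[str, bool],
    n_trees: int,
    seed: int,
) -> tuple[float, float]:
    """Out-of-bag NRMSE (continuous) and PFC (categorical) on the final fill."""
    sse, svar, mis, n_cat = 0.0, 0.0, 0, 0
    for t in traits:
        parts = [P.to_numpy(dtype=float)] if P.shape[1] else []
        for other in traits:
            if other == t:
                continue
            col = filled[other]
            parts.append(
                pd.get_dummies(col).to_numpy(dtype=float)
                if cat[other] else col.to_numpy(dtype=float)[:, None]
            )
        Xmat = np.hstack(parts) if parts else np.zeros((len(filled), 0))
        if Xmat.shape[1] == 0:
            continue
        if cat[t]:
            y = filled[t].astype(str).to_numpy()
            model = RandomForestClassifier(
                n_estimators=n_trees, max_features="sqrt", random_state=seed, oob_score=True, bootstrap=True
            )
            model.fit(Xmat, y)
            oob = model.oob_decision_function_
            ok = ~np.isnan(oob).any(axis=1)
            pred = model.classes_[oob[ok].argmax(axis=1)]
            mis += int((pred != y[ok]).sum())
            n_cat += int(ok.sum())
        else:
            y = filled[t].to_numpy(dtype=float)
            model = RandomForestRegressor(
                n_estimators=n_trees, max_features="sqrt", min_samples_leaf=5,
                random_state=seed, oob_score=True, bootstrap=True,
            )
            model.fit(Xmat, y)
            oob_pred = model.oob_prediction_
            var = y.var()
            if var > 0:
                sse += float(((oob_pred - y) ** 2).mean())
                svar += float(var)
    nrmse = float(np.sqrt(sse / svar)) if svar > 0 else float("nan")
    pfc = mis / n_cat if n_cat > 0 else float("nan")
    return nrmse, pfc
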