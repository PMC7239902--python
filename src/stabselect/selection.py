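"""Feature ranking and stability-oriented selection.

Four base rankers — two-sample t statistic, SVM-RFE, ReliefF and mRMR —
plus three selectors built for selection stability:

* ``ensemble_select``: Borda aggregation of the four rankings;
* ``bagged_t_select``: stability selection — t-ranking on 100 random
  half-size stratified subsamples, keeping the most frequently chosen
  features;
* ``wrapped_t_select``: the wrapped t-test.  Per iteration, each of 10
  frozen cross-validation folds selects the k features with the largest
  |t| + accumulated adjustment, an RBF-SVM trained on them is scored on
  the held-out fold, and the selected features' adjustments move up by a
  small delta when fold accuracy beats chance (down when below chance).
  Iteration stops once Kuncheva's index over the 10 fold selections has
  been exactly 1 for ``stable_runs`` consecutive iterations, yielding one
  consistent feature set.

Every selector returns exactly k features and is deterministic given its
inputs and seed.  Ties are broken by the primary score, then by |t|, then
by lexicographic feature id.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .matrix import FeatureMatrix
from .preprocessing import apply_zscore, fit_zscore
from .stability import kuncheva_index

DEFAULT_K = 10
DEFAULT_DELTA = 1e-4
DEFAULT_STABLE_RUNS = 100
DEFAULT_MAX_ITERATIONS = 100_000
#: Fixed SVM-RBF hyperparameters used inside the wrapped selector
#: (the evaluation module grid-searches the final reported models).
WRAPPED_SVM_C = 4.0
WRAPPED_SVM_GAMMA = 2.0 ** -4


@dataclass(frozen=True)
class RankedFeatures:
    """Feature ids ordered best-first with the ranking scores."""

    ids: tuple[str, ...]
    scores: tuple[float, ...]
    method: str

    def top(self, k: int) -> tuple[str, ...]:
        if k > len(self.ids):
            raise ValueError(f"requested {k} features from {len(self.ids)}")
        return self.ids[:k]


class ConvergenceError(RuntimeError):
    """Wrapped selection exceeded its iteration cap; carries the state."""

    def __init__(self, message, state):
        super().__init__(message)
        self.state = state


def _as_arrays(train, labels=None, feature_ids=None):
    if isinstance(train, FeatureMatrix):
        X, y = train.to_arrays()
        ids = list(train.feature_ids)
    else:
        X = np.asarray(train, dtype=float)
        y = np.asarray(labels)
        ids = list(feature_ids) if feature_ids is not None else [
            f"f{i}" for i in range(X.shape[1])]
    if len(np.unique(y)) != 2:
        raise ValueError("selection requires exactly two classes")
    return X, y.astype(int), ids


def _t_statistics(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Two-sample pooled-variance t statistic per feature (class 1 - class 0)."""
    a, b = X[y == 1], X[y == 0]
    n1, n2 = a.shape[0], b.shape[0]
    if min(n1, n2) < 2:
        raise ValueError("need at least two samples per class")
    var = (a.var(axis=0, ddof=1) * (n1 - 1) + b.var(axis=0, ddof=1) * (n2 - 1))
    sp = np.sqrt(var / (n1 + n2 - 2))
    se = sp * math.sqrt(1.0 / n1 + 1.0 / n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, (a.mean(axis=0) - b.mean(axis=0)) / se, 0.0)
    return t


def _ordered(primary: np.ndarray, tabs: np.ndarray, ids: list[str]) -> np.ndarray:
    """Indices sorted by descending primary score, then |t|, then id."""
    return np.lexsort((np.asarray(ids), -tabs, -primary))


def t_rank(train, labels=None, feature_ids=None) -> RankedFeatures:
    """Rank features by the absolute two-sample t statistic."""
    X, y, ids = _as_arrays(train, labels, feature_ids)
    tabs = np.abs(_t_statistics(X, y))
    order = _ordered(tabs, tabs, ids)
    return RankedFeatures(tuple(ids[i] for i in order),
                          tuple(float(tabs[i]) for i in order), "ttest")


def svm_rfe_rank(train, labels=None, feature_ids=None, C: float = 1.0,
                 step_fraction: float = 0.1) -> RankedFeatures:
    """Recursive feature elimination by linear-SVM weight magnitudes.

    Each iteration drops ``step_fraction`` (at least one) of the remaining
    features with the smallest |w|; the ranking is the reverse elimination
    order, with surviving features ordered by their final weights.
    """
    X, y, ids = _as_arrays(train, labels, feature_ids)
    tabs = np.abs(_t_statistics(X, y))
    remaining = list(range(X.shape[1]))
    eliminated: list[int] = []  # worst dropped first
    while remaining:
        clf = SVC(kernel="linear", C=C)
        clf.fit(X[:, remaining], y)
        w = np.abs(clf.coef_.ravel())
        order = _ordered(w, tabs[remaining], [ids[j] for j in remaining])
        n_drop = max(1, int(step_fraction * len(remaining)))
        if n_drop >= len(remaining):
            eliminated.extend(remaining[i] for i in order[::-1])
            break
        drop = [remaining[i] for i in order[-n_drop:]][::-1]  # worst first
        eliminated.extend(drop)
        drop_set = set(drop)
        remaining = [j for j in remaining if j not in drop_set]
    ranked = eliminated[::-1]
    p = len(ids)
    return RankedFeatures(tuple(ids[i] for i in ranked),
                          tuple(float(p - r) for r in range(p)), "svmrfe")


def relieff_rank(train, labels=None, feature_ids=None,
                 n_neighbors: int = 10) -> RankedFeatures:
    """ReliefF weights with k nearest hits/misses, every sample used once.

    Features are range-scaled so that single-feature differences lie in
    [0, 1]; weights accumulate mean miss-differences minus mean
    hit-differences.  ``n_neighbors`` is clipped to class size - 1.
    """
    if n_neighbors < 1:
        raise ValueError("n_neighbors must be >= 1")
    X, y, ids = _as_arrays(train, labels, feature_ids)
    n, p = X.shape
    span = X.max(axis=0) - X.min(axis=0)
    span[span == 0] = 1.0
    Xs = (X - X.min(axis=0)) / span

    counts = {c: int((y == c).sum()) for c in (0, 1)}
    if min(counts.values()) < 2:
        raise ValueError("need at least two samples per class for ReliefF")

    diff = np.abs(Xs[:, None, :] - Xs[None, :, :])  # n x n x p
    dist = diff.sum(axis=2)
    np.fill_diagonal(dist, np.inf)

    w = np.zeros(p)
    for i in range(n):
        same = np.flatnonzero(y == y[i])
        same = same[same != i]
        other = np.flatnonzero(y != y[i])
        k_hit = min(n_neighbors, same.size)
        k_miss = min(n_neighbors, other.size)
        hits = same[np.argsort(dist[i, same], kind="stable")[:k_hit]]
        misses = other[np.argsort(dist[i, other], kind="stable")[:k_miss]]
        w += diff[i, misses].mean(axis=0) - diff[i, hits].mean(axis=0)
    w /= n

    tabs = np.abs(_t_statistics(X, y))
    order = _ordered(w, tabs, ids)
    return RankedFeatures(tuple(ids[i] for i in order),
                          tuple(float(w[i]) for i in order), "relieff")


def _discretize_3bin(X: np.ndarray) -> np.ndarray:
    """Three levels split at mean - SD and mean + SD, per feature."""
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    out = np.ones(X.shape, dtype=np.int64)
    out[X < mean - sd] = 0
    out[X > mean + sd] = 2
    return out


def _mutual_information(a: np.ndarray, b: np.ndarray) -> float:
    """MI in nats between two small discrete arrays."""
    ja = np.unique(a, return_inverse=True)[1]
    jb = np.unique(b, return_inverse=True)[1]
    na, nb = ja.max() + 1, jb.max() + 1
    joint = np.bincount(ja * nb + jb, minlength=na * nb).reshape(na, nb)
    joint = joint / joint.sum()
    pa = joint.sum(axis=1, keepdims=True)
    pb = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float((joint[nz] * np.log(joint[nz] / (pa @ pb)[nz])).sum())


def mrmr_rank(train, labels=None, feature_ids=None,
              scheme: str = "difference") -> RankedFeatures:
    """Greedy minimum-redundancy maximum-relevance ranking.

    Features are discretised to three bins at mean +/- SD; relevance and
    redundancy are mutual information.  The default "difference" (MID)
    criterion maximises I(f; y) minus mean I(f; s) over already-selected s;
    "quotient" (MIQ) divides instead.  The selection order is the ranking.
    """
    if scheme not in ("difference", "quotient"):
        raise ValueError(f"unknown mRMR scheme {scheme!r}")
    X, y, ids = _as_arrays(train, labels, feature_ids)
    D = _discretize_3bin(X)
    p = X.shape[1]
    relevance = np.array([_mutual_information(D[:, j], y) for j in range(p)])
    tabs = np.abs(_t_statistics(X, y))

    pair_mi = np.full((p, p), np.nan)

    def _pair(i, j):
        if np.isnan(pair_mi[i, j]):
            pair_mi[i, j] = pair_mi[j, i] = _mutual_information(D[:, i], D[:, j])
        return pair_mi[i, j]

    selected: list[int] = []
    remaining = set(range(p))
    scores: list[float] = []
    while remaining:
        best, best_score = None, None
        cand = sorted(remaining)
        if not selected:
            crit = relevance[cand]
        else:
            red = np.array([np.mean([_pair(j, s) for s in selected]) for j in cand])
            if scheme == "difference":
                crit = relevance[cand] - red
            else:
                crit = relevance[cand] / np.maximum(red, 1e-12)
        order = _ordered(crit, tabs[cand], [ids[j] for j in cand])
        best = cand[order[0]]
        best_score = float(crit[order[0]])
        selected.append(best)
        remaining.discard(best)
        scores.append(best_score)
    return RankedFeatures(tuple(ids[i] for i in selected), tuple(scores), "mrmr")


# --------------------------------------------------------------------------
# stability-oriented selectors

def ensemble_select(train, labels=None, feature_ids=None,
                    k: int = DEFAULT_K) -> tuple[str, ...]:
    """Borda aggregation of the four base rankings; top k by rank sum.

    Lower rank sums win; ties are broken by |t| and then feature id.
    """
    X, y, ids = _as_arrays(train, labels, feature_ids)
    if k > len(ids):
        raise ValueError(f"requested {k} features from {len(ids)}")
    rankings = [t_rank(X, y, ids), svm_rfe_rank(X, y, ids),
                relieff_rank(X, y, ids), mrmr_rank(X, y, ids)]
    rank_sum = np.zeros(len(ids))
    pos = {fid: i for i, fid in enumerate(ids)}
    for ranking in rankings:
        for r, fid in enumerate(ranking.ids):
            rank_sum[pos[fid]] += r
    tabs = np.abs(_t_statistics(X, y))
    order = _ordered(-rank_sum, tabs, ids)
    return tuple(ids[i] for i in order[:k])


def bagged_t_select(train, labels=None, feature_ids=None, k: int = DEFAULT_K,
                    n_bags: int = 100, rng=None) -> tuple[str, ...]:
    """Stability selection: t-ranking on half-size stratified subsamples.

    Each bag draws floor(n_c / 2) samples per class without replacement,
    ranks by |t| and records its top k; the final set is the k most
    frequently recorded features (ties by mean |t| over bags, then id).
    """
    X, y, ids = _as_arrays(train, labels, feature_ids)
    if k > len(ids):
        raise ValueError(f"requested {k} features from {len(ids)}")
    rng = np.random.default_rng(rng)
    idx_by_class = {c: np.flatnonzero(y == c) for c in (0, 1)}
    half = {c: idx.size // 2 for c, idx in idx_by_class.items()}
    if min(half.values()) < 2:
        raise ValueError("classes too small to subsample at n/2")

    counts = np.zeros(len(ids))
    t_sums = np.zeros(len(ids))
    for _ in range(n_bags):
        rows = np.concatenate([
            rng.choice(idx_by_class[c], size=half[c], replace=False)
            for c in (0, 1)])
        tabs = np.abs(_t_statistics(X[rows], y[rows]))
        t_sums += tabs
        order = _ordered(tabs, tabs, ids)
        counts[order[:k]] += 1
    mean_t = t_sums / n_bags
    order = _ordered(counts, mean_t, ids)
    return tuple(ids[i] for i in order[:k])


@dataclass
class WrappedState:
    """Full trace of one wrapped t-test run.

    ``fold_selections[i][f]`` is the ordered tuple of ids fold f selected at
    iteration i; ``fold_accuracies`` the matching held-out accuracies; the
    adjustments vector accumulates +/- delta per fold selection per
    iteration.  ``consecutive_stable`` counts the trailing iterations with
    Kuncheva's index exactly 1.
    """

    feature_ids: tuple[str, ...]
    delta: float
    adjustments: np.ndarray = None
    iteration: int = 0
    fold_selections: list = field(default_factory=list)
    fold_accuracies: list = field(default_factory=list)
    ki_trajectory: list = field(default_factory=list)
    consecutive_stable: int = 0
    converged: bool = False
    fold_indices: list = field(default_factory=list)

    def __post_init__(self):
        if self.adjustments is None:
            self.adjustments = np.zeros(len(self.feature_ids))


def replay_adjustments(state: WrappedState) -> np.ndarray:
    """Re-execute the adjustment rule from the logged selections/accuracies.

    Independent of the selector internals: walks the recorded per-iteration
    fold selections and accuracies and re-accumulates +/- delta.
    """
    pos = {fid: i for i, fid in enumerate(state.feature_ids)}
    adj = np.zeros(len(state.feature_ids))
    for sels, accs in zip(state.fold_selections, state.fold_accuracies):
        for sel, acc in zip(sels, accs):
            idx = [pos[fid] for fid in sel]
            if acc > 0.5:
                adj[idx] += state.delta
            elif acc < 0.5:
                adj[idx] -= state.delta
    return adj


def wrapped_t_select(devset, labels=None, feature_ids=None, k: int = DEFAULT_K,
                     delta: float = DEFAULT_DELTA,
                     stable_runs: int = DEFAULT_STABLE_RUNS,
                     folds: int = 10, C: float = WRAPPED_SVM_C,
                     gamma: float = WRAPPED_SVM_GAMMA,
                     max_iterations: int = DEFAULT_MAX_ITERATIONS,
                     seed: int = 0) -> tuple[tuple[str, ...], WrappedState]:
    """Iteratively stabilised t-test selection (the wrapped t-test).

    The stratified fold partition is frozen for the whole run so the index
    measures selection stability rather than partition noise.  Per-fold
    base |t| statistics are fixed by the partition; only the accumulated
    adjustments evolve.  Terminates when KI = 1 for ``stable_runs``
    consecutive iterations, returning the common feature set and the full
    state; raises :class:`ConvergenceError` past ``max_iterations``.
    """
    X, y, ids = _as_arrays(devset, labels, feature_ids)
    p = len(ids)
    if k >= p:
        raise ValueError(f"need k < number of features, got k={k}, p={p}")

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_data = []
    fold_indices = []
    for tr, va in skf.split(X, y):
        params = fit_zscore(X[tr])
        Xtr = apply_zscore(params, X[tr])
        Xva = apply_zscore(params, X[va])
        base_t = np.abs(_t_statistics(Xtr, y[tr]))
        fold_data.append((Xtr, y[tr], Xva, y[va], base_t))
        fold_indices.append((tr.copy(), va.copy()))

    state = WrappedState(feature_ids=tuple(ids), delta=delta,
                         fold_indices=fold_indices)
    ids_arr = np.asarray(ids)
    acc_cache: dict[tuple[int, tuple], float] = {}

    while state.iteration < max_iterations:
        sels, accs = [], []
        for f, (Xtr, ytr, Xva, yva, base_t) in enumerate(fold_data):
            scores = base_t + state.adjustments
            order = np.lexsort((ids_arr, -base_t, -scores))
            sel_idx = tuple(int(i) for i in order[:k])
            key = (f, sel_idx)
            acc = acc_cache.get(key)
            if acc is None:
                cols = list(sel_idx)
                clf = SVC(kernel="rbf", C=C, gamma=gamma)
                clf.fit(Xtr[:, cols], ytr)
                acc = float((clf.predict(Xva[:, cols]) == yva).mean())
                acc_cache[key] = acc
            if acc > 0.5:
                state.adjustments[list(sel_idx)] += delta
            elif acc < 0.5:
                state.adjustments[list(sel_idx)] -= delta
            sels.append(tuple(ids_arr[list(sel_idx)]))
            accs.append(acc)
        ki = kuncheva_index([set(s) for s in sels], n_features=p)
        state.fold_selections.append(tuple(sels))
        state.fold_accuracies.append(tuple(accs))
        state.ki_trajectory.append(ki)
        state.iteration += 1
        if ki == 1.0:
            state.consecutive_stable += 1
        else:
            state.consecutive_stable = 0
        if state.consecutive_stable >= stable_runs:
            state.converged = True
            final = tuple(sorted(sels[0]))
            return final, state

    raise ConvergenceError(
        f"wrapped t-test did not stabilise within {max_iterations} iterations",
        state)


# --------------------------------------------------------------------------
# uniform selector interface for the evaluation engine

def make_selector(method: str, k: int = DEFAULT_K, **kwargs):
    """A ``selector(X, y, ids, rng) -> tuple of ids`` closure by name."""
    method = method.lower()
    if method in ("ttest", "t-test", "t"):
        return lambda X, y, ids, rng: t_rank(X, y, ids).top(k)
    if method in ("svmrfe", "svm-rfe", "rfe"):
        return lambda X, y, ids, rng: svm_rfe_rank(X, y, ids, **kwargs).top(k)
    if method == "relieff":
        return lambda X, y, ids, rng: relieff_rank(X, y, ids, **kwargs).top(k)
    if method == "mrmr":
        return lambda X, y, ids, rng: mrmr_rank(X, y, ids, **kwargs).top(k)
    if method == "ensemble":
        return lambda X, y, ids, rng: ensemble_select(X, y, ids, k=k)
    if method == "bagged":
        return lambda X, y, ids, rng: bagged_t_select(X, y, ids, k=k,
                                                      rng=rng, **kwargs)
    if method == "wrapped":
        def _wrapped(X, y, ids, rng):
            seed = int(np.random.default_rng(rng).integers(2 ** 31))
            sel, _ = wrapped_t_select(X, y, ids, k=k, seed=seed, **kwargs)
            return sel
        return _wrapped
    raise ValueError(f"unknown selection method {method!r}")

SELECTOR_NAMES = ("ttest", "svmrfe", "relieff", "mrmr", "ensemble",
                  "bagged", "wrapped")
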