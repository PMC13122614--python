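"""Additive (Shapley) feature attributions for the cascade stages.

Two routes are provided.  ``exact_shapley`` enumerates all coalitions of a
small feature set under the interventional value function (in-coalition
features from the explained instance, the rest from background rows,
averaged over the background) and applies the exact Shapley weights — it is
the oracle.  ``tree_attributions`` computes the same quantity for tree
ensembles in closed form: for a single background row, a decision tree's
value function restricted to one leaf is an indicator over coalitions
(path features whose constraint only the instance satisfies must be in the
coalition; features only the background satisfies must be out), and the
Shapley value of such an indicator game has a closed form, so attributions
are an exact sum over leaves and background rows — no sampling anywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.ensemble import ExtraTreesClassifier, GradientBoostingClassifier
from sklearn.tree import BaseDecisionTree

MAX_EXACT_FEATURES = 12

_FACT = np.array([math.factorial(i) for i in range(65)], dtype=float)


@dataclass
class AttributionResult:
    """Per-feature signed attributions for one explained instance.

    ``base_value + values.sum(axis=0)`` equals the model output for the
    instance (efficiency), per output column for vector-valued models.
    """

    feature_names: tuple[str, ...]
    values: np.ndarray  # (n_features,) or (n_features, n_outputs)
    base_value: float | np.ndarray

    @property
    def ranking(self) -> pd.DataFrame:
        mag = np.abs(self.values)
        if mag.ndim > 1:
            mag = mag.mean(axis=1)
        order = np.argsort(mag)[::-1]
        return pd.DataFrame(
            {
                "feature": [self.feature_names[i] for i in order],
                "mean_abs_attribution": mag[order],
            }
        )


def exact_shapley(
    predict_fn,
    instance: np.ndarray,
    background: np.ndarray,
    feature_idx: list[int] | None = None,
    feature_names: tuple[str, ...] | None = None,
) -> AttributionResult:
    """Brute-force Shapley values over all 2^M coalitions (M <= 12).

    ``predict_fn`` maps an (n, d) array to (n,) or (n, k) outputs.  The
    value of a coalition S is the mean prediction over background rows with
    the features in S replaced by the instance's values; features outside
    ``feature_idx`` always come from the background.
    """
    instance = np.asarray(instance, dtype=float).ravel()
    background = np.atleast_2d(np.asarray(background, dtype=float))
    d = instance.size
    idx = list(range(d)) if feature_idx is None else list(feature_idx)
    M = len(idx)
    if M > MAX_EXACT_FEATURES:
        raise ValueError(f"exact enumeration limited to {MAX_EXACT_FEATURES} features")

    def value(subset: tuple[int, ...]) -> np.ndarray:
        hybrid = background.copy()
        for j in subset:
            hybrid[:, j] = instance[j]
        return np.atleast_1d(np.asarray(predict_fn(hybrid)).mean(axis=0))

    cache = {
        subset: value(subset)
        for r in range(M + 1)
        for subset in combinations(idx, r)
    }
    out_dim = cache[()].size
    phi = np.zeros((d, out_dim))
    for i in idx:
        others = [j for j in idx if j != i]
        for r in range(M):
            w = _FACT[r] * _FACT[M - r - 1] / _FACT[M]
            for subset in combinations(others, r):
                with_i = tuple(sorted(subset + (i,)))
                phi[i] += w * (cache[with_i] - cache[subset])
    base = cache[()]
    names = feature_names or tuple(f"x{i}" for i in range(d))
    if out_dim == 1:
        return AttributionResult(names, phi[:, 0], float(base[0]))
    return AttributionResult(names, phi, base)


# ------------------------------------------------------------- tree closed form


def _leaf_paths(tree) -> list[tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]]:
    """(value, path_features, lower_bounds, upper_bounds) per reachable leaf.

    A sample satisfies a path feature's combined constraint iff
    lower < x[f] <= upper (sklearn sends x[f] <= threshold left).
    """
    leaves = []
    stack: list[tuple[int, dict[int, tuple[float, float]]]] = [(0, {})]
    feat = tree.feature
    thr = tree.threshold
    left, right = tree.children_left, tree.children_right
    while stack:
        node, cons = stack.pop()
        if left[node] == -1:  # leaf
            items = sorted(cons.items())
            leaves.append(
                (
                    tree.value[node].ravel().copy(),
                    np.array([f for f, _ in items], dtype=int),
                    np.array([lo for _, (lo, _) in items]),
                    np.array([hi for _, (_, hi) in items]),
                )
            )
            continue
        f, t = int(feat[node]), float(thr[node])
        lo, hi = cons.get(f, (-np.inf, np.inf))
        if t < hi:  # left: x <= t
            cl = dict(cons)
            cl[f] = (lo, min(hi, t))
            stack.append((int(left[node]), cl))
        if t >= lo:  # right: x > t  (skip only if max(lo,t)=lo already)
            cr = dict(cons)
            cr[f] = (max(lo, t), hi)
            if cr[f][0] < cr[f][1]:
                stack.append((int(right[node]), cr))
    return leaves


def _tree_shapley(
    leaves, x: np.ndarray, background: np.ndarray, n_out: int
) -> tuple[np.ndarray, np.ndarray]:
    """Exact interventional Shapley for one tree, averaged over background."""
    n_bg, d = background.shape
    phi = np.zeros((d, n_out))
    base = np.zeros(n_out)
    for value, feats, lo, hi in leaves:
        v = value if value.size == n_out else np.full(n_out, value[0])
        if feats.size == 0:  # constant tree
            base += v
            continue
        bx = background[:, feats]
        sx = (x[feats] > lo) & (x[feats] <= hi)  # (p,)
        sb = (bx > lo) & (bx <= hi)  # (n_bg, p)
        dead = (~sx & ~sb).any(axis=1)
        A = sx & ~sb
        B = ~sx & sb
        a = A.sum(axis=1)
        m = a + B.sum(axis=1)
        live = ~dead
        # base: leaf reached with every feature from the background (S = empty)
        base += v * np.mean(live & (a == 0))
        rows = np.flatnonzero(live & (m > 0))
        if rows.size == 0:
            continue
        ar, mr = a[rows], m[rows]
        wpos = np.where(ar >= 1, _FACT[np.maximum(ar - 1, 0)] * _FACT[mr - ar] / _FACT[mr], 0.0)
        wneg = np.where(mr - ar >= 1, _FACT[ar] * _FACT[np.maximum(mr - ar - 1, 0)] / _FACT[mr], 0.0)
        coef = A[rows] * wpos[:, None] - B[rows] * wneg[:, None]  # (rows, p)
        contrib = coef.sum(axis=0) / n_bg  # (p,)
        phi[feats] += np.outer(contrib, v)
    return phi, base


def _ensemble_terms(model) -> tuple[list, float | np.ndarray, int]:
    """Decompose a supported model into (scaled per-tree leaf sets, offset)."""
    if isinstance(model, GradientBoostingClassifier):
        if model.n_classes_ != 2:
            raise ValueError("only binary gradient-boosting stages are supported")
        terms = [
            (_leaf_paths(est.tree_), model.learning_rate)
            for est in model.estimators_[:, 0]
        ]
        return terms, None, 1
    if isinstance(model, ExtraTreesClassifier):
        k = model.n_classes_
        terms = []
        for est in model.estimators_:
            leaves = []
            for value, feats, lo, hi in _leaf_paths(est.tree_):
                probs = value / value.sum() if value.sum() > 0 else value
                leaves.append((probs, feats, lo, hi))
            terms.append((leaves, 1.0 / model.n_estimators))
        return terms, 0.0, k
    if isinstance(model, BaseDecisionTree):
        return [(_leaf_paths(model.tree_), 1.0)], 0.0, model.tree_.value.shape[-1]
    raise ValueError(f"unsupported model type {type(model).__name__}")


def tree_attributions(
    model,
    X_explain: np.ndarray,
    background: np.ndarray,
    feature_names: tuple[str, ...] | None = None,
) -> list[AttributionResult]:
    """Exact interventional Shapley attributions for a tree ensemble stage.

    Gradient-boosted stages are explained on the raw margin (log-odds)
    scale; extremely-randomized-trees stages on class probabilities.
    Agreement with ``exact_shapley`` on small models is exact up to float
    round-off.
    """
    X_explain = np.atleast_2d(np.asarray(X_explain, dtype=float))
    background = np.atleast_2d(np.asarray(background, dtype=float))
    d = X_explain.shape[1]
    names = feature_names or tuple(f"x{i}" for i in range(d))

    terms, _, n_out = _ensemble_terms(model)
    offset = 0.0
    if isinstance(model, GradientBoostingClassifier):
        # constant prior: raw margin minus the tree sum at any point
        ref = background[:1]
        tree_sum = sum(
            scale * _eval_leaves(leaves, ref[0]) for leaves, scale in terms
        )
        offset = float(model.decision_function(ref)[0]) - float(tree_sum)

    results = []
    for x in X_explain:
        phi = np.zeros((d, n_out))
        base = np.zeros(n_out) + offset
        for leaves, scale in terms:
            p, b = _tree_shapley(leaves, x, background, n_out)
            phi += scale * p
            base += scale * b
        if n_out == 1:
            results.append(AttributionResult(names, phi[:, 0], float(base[0])))
        else:
            results.append(AttributionResult(names, phi, base))
    return results


def _eval_leaves(leaves, x: np.ndarray) -> float:
    for value, feats, lo, hi in leaves:
        if feats.size == 0 or np.all((x[feats] > lo) & (x[feats] <= hi)):
            return float(value.ravel()[0])
    raise RuntimeError("no leaf matched")  # pragma: no cover


def rank_features(
    attributions: list[AttributionResult], top: int | None = None
) -> pd.DataFrame:
    """Features ordered by mean absolute attribution over the explained set."""
    if not attributions:
        raise ValueError("no attributions to rank")
    names = attributions[0].feature_names
    mags = []
    for res in attributions:
        mag = np.abs(res.values)
        if mag.ndim > 1:
            mag = mag.mean(axis=1)
        mags.append(mag)
    mean_abs = np.mean(mags, axis=0)
    order = np.argsort(mean_abs)[::-1]
    if top is not None:
        order = order[:top]
    return pd.DataFrame(
        {
            "feature": [names[i] for i in order],
            "mean_abs_attribution": mean_abs[order],
        }
    ).reset_index(drop=True)


def cascade_attributions(
    model,
    X: np.ndarray,
    background: np.ndarray,
    max_background: int = 100,
    seed: int = 0,
) -> tuple[list[AttributionResult], np.ndarray]:
    """Species-level attributions routed through the cascade.

    Each test row is attributed by the stage that finalized its label
    (stage 1 for Vespidae rows, stage 2 for Apis, stage 3 for Bombus); the
    background is a seeded subset of training rows.  Returns the per-row
    attribution results and the finalizing stage index (1, 2 or 3).
    """
    from .cascade import predict_cascade

    X = np.atleast_2d(np.asarray(X, dtype=float))
    background = np.atleast_2d(np.asarray(background, dtype=float))
    if len(background) > max_background:
        rng = np.random.default_rng(seed)
        background = background[
            rng.choice(len(background), size=max_background, replace=False)
        ]
    pred = predict_cascade(model, X)
    stages = np.where(
        pred["family"] == "Vespidae", 1, np.where(pred["genus"] == "Apis", 2, 3)
    )
    results: list[AttributionResult] = [None] * len(X)  # type: ignore[list-item]
    stage_models = {1: model.stage1, 2: model.stage2, 3: model.stage3}
    for s in (1, 2, 3):
        rows = np.flatnonzero(stages == s)
        if rows.size == 0:
            continue
        res = tree_attributions(
            stage_models[s], X[rows], background, feature_names=model.feature_names
        )
        for r, out in zip(rows, res):
            results[r] = out
    return results, stages
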