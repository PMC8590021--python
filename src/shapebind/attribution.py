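"""Exact interventional Shapley attribution for tree ensembles.

For a decision tree, the prediction under a feature coalition S follows the
explained sample x on features in S and a background sample z elsewhere.
Each leaf's path constrains a small set of features; after consolidating
the path's splits into one interval per feature, the leaf is reached under
coalition S exactly when S contains every feature whose interval only x
satisfies (the set A) and excludes every feature only z satisfies (the set
B) -- features satisfied by both are irrelevant, and a feature satisfied by
neither makes the leaf unreachable for the pair.  The Shapley value of this
reachability game has a closed form: each feature in A receives
``v * (a-1)! b! / (a+b)!`` and each feature in B receives
``-v * a! (b-1)! / (a+b)!`` where ``v`` is the leaf value and a = |A|,
b = |B|.  Summing over leaves, averaging over a background sample set and
over the forest's trees gives exact interventional Shapley values
satisfying local accuracy: base value + sum of contributions = prediction.

Global importance is the mean absolute contribution per feature over an
explained sample set; the top-k features are categorized by shape class
(intra- vs inter-base-pair, MGW kept as its own class) and by core vs
flank position.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import factorial
from typing import Sequence

import numpy as np
import pandas as pd

from .shape import FEATURE_NAMES, INTER_FEATURES, INTRA_FEATURES, parse_feature_name


@dataclass
class AttributionRecord:
    """Per-feature Shapley contributions for a set of explained samples."""

    feature_names: list[str]
    contributions: np.ndarray  # (n_samples, n_features)
    base_value: float  # expected model output over the background


@dataclass
class _LeafPaths:
    """Consolidated leaf constraints of one tree.

    For leaf l with k_l constrained features: ``features[l]`` (int array),
    ``lower[l]`` / ``upper[l]`` (pass iff lower < x[f] <= upper), ``value[l]``.
    """

    features: list[np.ndarray]
    lower: list[np.ndarray]
    upper: list[np.ndarray]
    values: np.ndarray


def _extract_leaf_paths(tree) -> _LeafPaths:
    t = tree.tree_
    feats: list[np.ndarray] = []
    lows: list[np.ndarray] = []
    ups: list[np.ndarray] = []
    vals: list[float] = []

    def walk(node: int, constraints: dict[int, tuple[float, float]]) -> None:
        if t.children_left[node] == -1:
            items = sorted(constraints.items())
            feats.append(np.array([f for f, _ in items], dtype=np.intp))
            lows.append(np.array([c[0] for _, c in items]))
            ups.append(np.array([c[1] for _, c in items]))
            vals.append(float(t.value[node].ravel()[0]))
            return
        f, thr = int(t.feature[node]), float(t.threshold[node])
        lo, hi = constraints.get(f, (-np.inf, np.inf))
        # left: x[f] <= thr ; right: x[f] > thr
        left = dict(constraints)
        left[f] = (lo, min(hi, thr))
        walk(int(t.children_left[node]), left)
        right = dict(constraints)
        right[f] = (max(lo, thr), hi)
        walk(int(t.children_right[node]), right)

    walk(0, {})
    return _LeafPaths(feats, lows, ups, np.array(vals))


def _shapley_weights(max_k: int) -> tuple[np.ndarray, np.ndarray]:
    """WA[a,b] = (a-1)! b! / (a+b)! and WB[a,b] = a! (b-1)! / (a+b)!."""
    fact = np.array([factorial(i) for i in range(max_k + 1)], dtype=float)
    WA = np.zeros((max_k + 1, max_k + 1))
    WB = np.zeros((max_k + 1, max_k + 1))
    for a in range(max_k + 1):
        for b in range(max_k + 1 - a):
            if a > 0:
                WA[a, b] = fact[a - 1] * fact[b] / fact[a + b]
            if b > 0:
                WB[a, b] = fact[a] * fact[b - 1] / fact[a + b]
    return WA, WB


def _tree_contributions(
    paths: _LeafPaths, X: np.ndarray, Z: np.ndarray, n_features: int
) -> np.ndarray:
    """(n_samples, n_features) Shapley values of one tree, background-averaged."""
    S, G = len(X), len(Z)
    max_k = max((len(f) for f in paths.features), default=0)
    WA, WB = _shapley_weights(max_k)
    phi = np.zeros((S, n_features))
    for feats, lo, hi, v in zip(
        paths.features, paths.lower, paths.upper, paths.values
    ):
        if len(feats) == 0:
            continue  # constant tree: contributes to base and f(x) equally
        Px = (X[:, feats] > lo) & (X[:, feats] <= hi)  # S x k
        Pz = (Z[:, feats] > lo) & (Z[:, feats] <= hi)  # G x k
        A = Px[:, None, :] & ~Pz[None, :, :]  # S x G x k
        B = ~Px[:, None, :] & Pz[None, :, :]
        dead = (~Px[:, None, :] & ~Pz[None, :, :]).any(axis=2)
        a = A.sum(axis=2)
        b = B.sum(axis=2)
        wa = np.where(dead, 0.0, v * WA[a, b])  # S x G
        wb = np.where(dead, 0.0, -v * WB[a, b])
        contrib = (A * wa[:, :, None]).sum(axis=1) + (B * wb[:, :, None]).sum(axis=1)
        phi[:, feats] += contrib / G
    return phi


def tree_shap(
    predictor,
    samples: np.ndarray,
    background: np.ndarray,
    feature_names: Sequence[str] | None = None,
) -> AttributionRecord:
    """Exact interventional Shapley values for a trained forest.

    ``predictor`` is a :class:`~shapebind.training.TrainedPredictor` or a
    fitted sklearn forest/tree.  ``background`` is the reference sample the
    interventional expectations are taken over (non-empty).
    """
    model = getattr(predictor, "model", predictor)
    names = feature_names or getattr(predictor, "feature_names", None)
    X = np.atleast_2d(np.asarray(samples, dtype=float))
    Z = np.atleast_2d(np.asarray(background, dtype=float))
    if len(Z) == 0:
        raise ValueError("background must be non-empty")
    if names is not None and len(names) != X.shape[1]:
        raise ValueError("feature_names length does not match samples")
    estimators = getattr(model, "estimators_", [model])
    n_features = X.shape[1]
    phi = np.zeros((len(X), n_features))
    for est in estimators:
        phi += _tree_contributions(_extract_leaf_paths(est), X, Z, n_features)
    phi /= len(estimators)
    base = float(np.mean(model.predict(Z)))
    return AttributionRecord(
        feature_names=list(names) if names is not None else
        [f"f{i}" for i in range(n_features)],
        contributions=phi,
        base_value=base,
    )


def brute_force_shap(
    model, x: np.ndarray, background: np.ndarray, features: Sequence[int]
) -> np.ndarray:
    """Subset-enumeration interventional Shapley oracle (2^M, M <= ~15).

    Only the listed features are treated as players; all others must be
    unused by the model (they receive 0 by the dummy axiom).
    """
    x = np.asarray(x, dtype=float)
    Z = np.atleast_2d(np.asarray(background, dtype=float))
    M = len(features)
    fact = [factorial(i) for i in range(M + 1)]

    def value(S: frozenset) -> float:
        pts = np.repeat(Z.copy(), 1, axis=0)
        for f in S:
            pts[:, f] = x[f]
        return float(np.mean(model.predict(pts)))

    cache: dict[frozenset, float] = {}

    def v(S: frozenset) -> float:
        if S not in cache:
            cache[S] = value(S)
        return cache[S]

    phi = np.zeros(len(x))
    for i in features:
        others = [f for f in features if f != i]
        total = 0.0
        for k in range(M):
            for S in combinations(others, k):
                S = frozenset(S)
                w = fact[k] * fact[M - k - 1] / fact[M]
                total += w * (v(S | {i}) - v(S))
        phi[i] = total
    return phi


@dataclass
class ImportanceReport:
    """Global feature ranking by mean |Shapley contribution|."""

    ranking: list[str]
    mean_abs: pd.Series  # indexed by feature name, in ranking order
    top_k: list[str]


def _canonical_order_key(name: str) -> tuple:
    """Position-major, fixed-feature-order tie-break key.

    Names that are not feature@position sort after all shape features, by
    string, so the ranking stays total on foreign feature names.
    """
    try:
        feat, pos = parse_feature_name(name)
    except ValueError:
        return (9, 0, 0, name)
    if pos.startswith("+"):
        region, p = 2, int(pos[1:])
    elif pos.startswith("-"):
        region, p = 0, int(pos)
    else:
        region, p = 1, int(pos)
    return (region, p, FEATURE_NAMES.index(feat), name)


def global_importance(
    record: AttributionRecord, k: int = 5
) -> ImportanceReport:
    """Rank features by mean absolute contribution over the explained samples.

    Ties are broken by canonical (position, feature) order so rankings are
    reproducible bit-for-bit.
    """
    mean_abs = np.abs(record.contributions).mean(axis=0)
    names = record.feature_names
    order = sorted(
        range(len(names)),
        key=lambda i: (-mean_abs[i], _canonical_order_key(names[i])),
    )
    ranking = [names[i] for i in order]
    if k > len(ranking):
        warnings.warn(
            f"k={k} exceeds {len(ranking)} features; returning full ranking",
            stacklevel=2,
        )
        k = len(ranking)
    return ImportanceReport(
        ranking=ranking,
        mean_abs=pd.Series(mean_abs[order], index=ranking),
        top_k=ranking[:k],
    )


def categorize(report: ImportanceReport, motif_length: int) -> dict[str, float]:
    """Fractions of the top-k features by shape class and genomic region.

    MGW is its own class, excluded from the intra/inter split; region is
    core (positions 1..m) vs flank (signed positions).
    """
    top = report.top_k
    if not top:
        warnings.warn("empty top-feature list; all fractions 0", stacklevel=2)
        return {
            "intra": 0.0, "inter": 0.0, "mgw": 0.0, "core": 0.0, "flank": 0.0,
        }
    n_intra = n_inter = n_mgw = n_core = 0
    for name in top:
        feat, pos = parse_feature_name(name)
        if feat == "MGW":
            n_mgw += 1
        elif feat in INTRA_FEATURES:
            n_intra += 1
        elif feat in INTER_FEATURES:
            n_inter += 1
        if not pos.startswith(("+", "-")):
            if not 1 <= int(pos) <= motif_length:
                raise ValueError(f"core position {pos} outside 1..{motif_length}")
            n_core += 1
    n = len(top)
    n_base_pair = n_intra + n_inter
    return {
        "intra": n_intra / n_base_pair if n_base_pair else 0.0,
        "inter": n_inter / n_base_pair if n_base_pair else 0.0,
        "mgw": n_mgw / n,
        "core": n_core / n,
        "flank": (n - n_core) / n,
    }
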