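"""Random-forest affinity regression with randomized search and PR evaluation.

The regressor learns normalized peak height (0-1000) from the flattened
shape features.  Hyperparameters are chosen by seeded randomized search
(default 75 distinct draws from n_estimators 10-200, max_features
{all, sqrt, log2}, max_depth 4-12) under k-fold cross-validated weighted
MSE computed on the training split only; the winner is refit on the full
training split.  Bound-vs-unbound ranking quality is measured as the area
under the precision-recall curve (average-precision convention) on the
held-out validation split, against the motif log-odds score as the
motif-only baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold


@dataclass
class HyperparameterSpace:
    """Randomized-search space for the forest."""

    n_trees: tuple[int, int] = (10, 200)
    max_features_rules: tuple[str, ...] = ("all", "sqrt", "log2")
    max_depth: tuple[int, int] = (4, 12)
    iterations: int = 75
    folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")

    @property
    def size(self) -> int:
        return (
            (self.n_trees[1] - self.n_trees[0] + 1)
            * len(self.max_features_rules)
            * (self.max_depth[1] - self.max_depth[0] + 1)
        )

    def sample(self) -> list[tuple[int, str, int]]:
        """Seeded uniform draws without replacement, capped at the space size."""
        rng = np.random.default_rng(self.seed)
        n = min(self.iterations, self.size)
        seen: set[tuple[int, str, int]] = set()
        out: list[tuple[int, str, int]] = []
        while len(out) < n:
            cand = (
                int(rng.integers(self.n_trees[0], self.n_trees[1] + 1)),
                self.max_features_rules[int(rng.integers(len(self.max_features_rules)))],
                int(rng.integers(self.max_depth[0], self.max_depth[1] + 1)),
            )
            if cand not in seen:
                seen.add(cand)
                out.append(cand)
        return out


def _sklearn_max_features(rule: str):
    # "auto" / "all" historically meant every feature for a regressor
    return {"all": 1.0, "auto": 1.0, "sqrt": "sqrt", "log2": "log2"}[rule]


@dataclass
class TrainedPredictor:
    """Fitted forest plus the provenance needed to reuse and audit it."""

    model: RandomForestRegressor
    chosen_params: tuple[int, str, int]
    feature_names: list[str]
    label_range: tuple[float, float]
    cv_report: pd.DataFrame  # one row per candidate: params + mean CV loss
    seed: int
    n_fits: int = 0

    def predict(self, X, feature_names: Sequence[str] | None = None) -> np.ndarray:
        """Ensemble-mean predictions; names checked when provided."""
        if feature_names is not None:
            if list(feature_names) != self.feature_names:
                first = next(
                    (a, b)
                    for a, b in zip(
                        list(feature_names) + ["<missing>"] * len(self.feature_names),
                        self.feature_names + ["<missing>"] * len(feature_names),
                    )
                    if a != b
                )
                raise ValueError(
                    f"feature name mismatch: got {first[0]!r}, expected {first[1]!r}"
                )
        return self.model.predict(np.asarray(X))


def _weighted_mse(y, yhat, w) -> float:
    w = np.asarray(w, dtype=float)
    return float(np.average((np.asarray(y) - np.asarray(yhat)) ** 2, weights=w))


def train(
    X: np.ndarray,
    y: np.ndarray,
    sample_weight: np.ndarray,
    feature_names: Sequence[str],
    space: HyperparameterSpace | None = None,
) -> TrainedPredictor:
    """Randomized search + k-fold CV on (X, y, w); refit winner on all rows.

    The caller passes the *training split only*; the validation split never
    enters model selection.
    """
    space = space or HyperparameterSpace()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(sample_weight, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("training data contains a single class of labels")
    candidates = space.sample()
    kf = KFold(n_splits=space.folds, shuffle=True, random_state=space.seed)
    folds = list(kf.split(X))
    n_fits = 0
    rows = []
    for n_trees, mf_rule, depth in candidates:
        losses = []
        for tr, te in folds:
            rf = RandomForestRegressor(
                n_estimators=n_trees,
                max_features=_sklearn_max_features(mf_rule),
                max_depth=depth,
                random_state=space.seed,
                n_jobs=1,
            )
            rf.fit(X[tr], y[tr], sample_weight=w[tr])
            n_fits += 1
            losses.append(_weighted_mse(y[te], rf.predict(X[te]), w[te]))
        rows.append(
            {
                "n_estimators": n_trees,
                "max_features": mf_rule,
                "max_depth": depth,
                "mean_cv_mse": float(np.mean(losses)),
            }
        )
    report = pd.DataFrame(rows)
    best = int(report["mean_cv_mse"].idxmin())
    n_trees, mf_rule, depth = candidates[best]
    final = RandomForestRegressor(
        n_estimators=n_trees,
        max_features=_sklearn_max_features(mf_rule),
        max_depth=depth,
        random_state=space.seed,
        n_jobs=1,
    )
    final.fit(X, y, sample_weight=w)
    n_fits += 1
    return TrainedPredictor(
        model=final,
        chosen_params=(n_trees, mf_rule, depth),
        feature_names=list(feature_names),
        label_range=(float(y.min()), float(y.max())),
        cv_report=report,
        seed=space.seed,
        n_fits=n_fits,
    )


@dataclass
class PRCurve:
    """Precision-recall curve with average-precision area."""

    thresholds: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    auprc: float
    positives: int


def pr_curve(scores: Sequence[float], bound_flags: Sequence[bool]) -> PRCurve:
    """Precision/recall at every distinct score threshold (descending).

    Ties are grouped at one threshold.  The area is the average-precision
    step sum sum_k precision_k * (recall_k - recall_{k-1}), not the
    trapezoid, because the two differ on coarse curves.
    """
    scores = np.asarray(scores, dtype=float)
    flags = np.asarray(bound_flags, dtype=bool)
    n_pos = int(flags.sum())
    if n_pos == 0:
        raise ValueError("PR curve undefined without positive examples")
    order = np.argsort(-scores, kind="stable")
    s, f = scores[order], flags[order]
    # last index of each tie group
    distinct = np.nonzero(np.diff(s))[0]
    cut = np.r_[distinct, len(s) - 1]
    tp = np.cumsum(f)[cut]
    n_pred = cut + 1
    precision = tp / n_pred
    recall = tp / n_pos
    prev_recall = np.r_[0.0, recall[:-1]]
    auprc = float(np.sum(precision * (recall - prev_recall)))
    return PRCurve(
        thresholds=s[cut],
        precision=precision,
        recall=recall,
        auprc=auprc,
        positives=n_pos,
    )


def baseline_auprc(
    pwm_scores: Sequence[float], bound_flags: Sequence[bool]
) -> PRCurve:
    """Motif-only comparator: rank the same sites by PWM log-odds score."""
    return pr_curve(pwm_scores, bound_flags)


def evaluate(dataset, predictor: TrainedPredictor, b: int) -> PRCurve:
    """Validation-split PR curve of the predictor at border b."""
    Xv, _, _, cols = dataset.design(b, dataset.val_idx)
    preds = predictor.predict(Xv, feature_names=cols)
    flags = dataset.sites["bound"].to_numpy()[dataset.val_idx]
    return pr_curve(preds, flags)


def train_and_evaluate(
    dataset,
    b: int = 4,
    space: HyperparameterSpace | None = None,
) -> tuple[TrainedPredictor, PRCurve, PRCurve]:
    """Train at border b; return (predictor, model PR, motif-baseline PR)."""
    Xt, yt, wt, cols = dataset.design(b, dataset.train_idx)
    predictor = train(Xt, yt, wt, cols, space)
    model_pr = evaluate(dataset, predictor, b)
    val_flags = dataset.sites["bound"].to_numpy()[dataset.val_idx]
    val_scores = dataset.sites["score"].to_numpy()[dataset.val_idx]
    base_pr = baseline_auprc(val_scores, val_flags)
    return predictor, model_pr, base_pr


def width_sweep(
    dataset,
    widths: Sequence[int],
    space: HyperparameterSpace | None = None,
) -> pd.DataFrame:
    """Validation AUPRC per border width, same splits and seeds throughout."""
    for b in widths:
        if b < 0 or b > dataset.max_border:
            raise ValueError(
                f"width {b} outside precomputed range [0, {dataset.max_border}]"
            )
    rows = []
    for b in widths:
        _, model_pr, _ = train_and_evaluate(dataset, b, space)
        rows.append({"border": b, "auprc": model_pr.auprc})
    return pd.DataFrame(rows)


def plot_pr_curves(curves: dict[str, PRCurve], path) -> None:
    """Optional PR-curve plot (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for label, c in curves.items():
        ax.step(
            np.r_[c.recall, 1.0], np.r_[c.precision, c.precision[-1]],
            where="post", label=f"{label} (AUPRC={c.auprc:.3f})",
        )
    ax.set_xlabel("recall")
    ax.set_ylabel("precision")
    ax.set_ylim(0, 1.05)
    ax.legend(loc="lower left")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
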