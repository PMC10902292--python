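"""Class-balanced boosted-tree decoding of maze section from gamma elements.

The classifier is a boosted ensemble of depth-limited decision trees with
per-iteration random undersampling to class balance (RUSBoost-style): at each
boosting round every class is randomly downsampled to the size of the rarest
class before the tree is fitted, which lets rare maze sections (reward field,
target arm) be learned despite heavy class imbalance, and makes 1/n_classes
the correct chance level.  Boosting uses multiclass SAMME weighting with a
slow learning rate.

Evaluation is 4-fold cross-validation with folds that partition theta cycles,
never elements, so two elements from the same cycle cannot straddle the
train/test boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import GroupKFold
from sklearn.tree import DecisionTreeClassifier

from .gammael import FEATURES, GAMMA_FEATURES, THETA_FEATURES

FEATURE_SETS = {
    "theta+gamma": FEATURES,
    "gamma": GAMMA_FEATURES,
    "theta": THETA_FEATURES,
}


@dataclass
class DecoderConfig:
    max_splits: int = 500
    max_learners: int = 500
    learn_rate: float = 0.01
    n_folds: int = 4
    feature_set: str = "theta+gamma"
    label_scheme: str = "standard"   # or "alternative-arm"
    seed: int = 0

    @property
    def features(self) -> list[str]:
        return FEATURE_SETS[self.feature_set]

    @property
    def label_column(self) -> str:
        return "section" if self.label_scheme == "standard" else "section_alt"


class RUSBoostClassifier:
    """Boosted decision trees with per-iteration random undersampling.

    SAMME-weighted boosting; each round draws an exactly class-balanced
    training subset (every class downsampled to the rarest class count, so
    per-round class counts differ by at most 1 — they are equal) and fits a
    tree limited to ``max_splits`` decision splits.
    """

    def __init__(self, n_estimators: int = 500, learning_rate: float = 0.01,
                 max_splits: int = 500, random_state: int | None = None):
        self.n_estimators = n_estimators
        self.learning_rate = learning_rate
        self.max_splits = max_splits
        self.random_state = random_state

    def _balanced_indices(self, y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        counts = {c: np.nonzero(y == c)[0] for c in self.classes_}
        m = min(len(v) for v in counts.values())
        idx = np.concatenate([rng.choice(v, m, replace=False)
                              for v in counts.values()])
        rng.shuffle(idx)
        return idx

    def fit(self, X: np.ndarray, y: np.ndarray) -> "RUSBoostClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        K = len(self.classes_)
        if K < 2:
            raise ValueError("need at least 2 classes")
        rng = np.random.default_rng(self.random_state)
        n = len(y)
        w = np.full(n, 1.0 / n)
        self.estimators_: list[DecisionTreeClassifier] = []
        self.alphas_: list[float] = []
        for t in range(self.n_estimators):
            idx = self._balanced_indices(y, rng)
            tree = DecisionTreeClassifier(
                max_leaf_nodes=self.max_splits + 1,
                random_state=int(rng.integers(2**31 - 1)))
            sw = w[idx]
            tree.fit(X[idx], y[idx], sample_weight=sw / sw.sum())
            pred = tree.predict(X)
            miss = pred != y
            eps = float(np.sum(w * miss))
            if eps >= 1.0 - 1.0 / K:
                continue  # worse than chance on this draw; discard round
            eps = max(eps, 1e-10)
            alpha = self.learning_rate * (np.log((1 - eps) / eps) + np.log(K - 1))
            self.estimators_.append(tree)
            self.alphas_.append(alpha)
            w = w * np.exp(alpha * miss)
            w /= w.sum()
        if not self.estimators_:
            raise RuntimeError("boosting failed: no usable round")
        return self

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        scores = np.zeros((len(X), len(self.classes_)))
        lut = {c: i for i, c in enumerate(self.classes_)}
        for tree, alpha in zip(self.estimators_, self.alphas_):
            pred = tree.predict(X)
            for i, p in enumerate(pred):
                scores[i, lut[p]] += alpha
        return scores

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self.decision_scores(X), axis=1)]


@dataclass
class PerformanceReport:
    per_class: pd.Series                 # correct fraction per class
    confusion: pd.DataFrame              # rows true, cols predicted (counts)
    overall: float                       # correct fraction over all elements
    class_mean: float                    # mean of per-class fractions
    chance: float
    ci_low: float                        # bootstrap CI on the overall fraction
    ci_high: float
    n_per_class: pd.Series
    predictions: pd.DataFrame = field(repr=False, default=None)

    def above_chance(self) -> bool:
        return self.ci_low > self.chance

    def within_chance(self) -> bool:
        return self.ci_low <= self.chance <= self.ci_high


def _design(table: pd.DataFrame, config: DecoderConfig):
    X = table[config.features].to_numpy(dtype=float)
    y = table[config.label_column].to_numpy()
    groups = (table["trial"].astype(str) + "/" + table["cycle_id"].astype(str)
              ).to_numpy()
    return X, y, groups


def train_location_classifier(table: pd.DataFrame,
                              config: DecoderConfig) -> RUSBoostClassifier:
    """Fit the balanced boosted ensemble on the full element table."""
    X, y, groups = _design(table, config)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    for c, cnt in zip(classes, counts):
        ncyc = len(np.unique(groups[y == c]))
        if ncyc < config.n_folds:
            raise ValueError(f"class {c!r} has only {ncyc} cycles "
                             f"(need >= {config.n_folds})")
    model = RUSBoostClassifier(
        n_estimators=config.max_learners, learning_rate=config.learn_rate,
        max_splits=config.max_splits, random_state=config.seed)
    model.fit(X, y)
    model.config = config
    return model


def evaluate_crossval(table: pd.DataFrame, config: DecoderConfig,
                      n_boot: int = 1000) -> PerformanceReport:
    """Cycle-grouped 4-fold cross-validated performance.

    Folds partition theta cycles; predictions for every element come from a
    model that never saw that element's cycle.  The bootstrap CI (with
    replacement over elements) is on the overall correct fraction.
    """
    X, y, groups = _design(table, config)
    uniq = np.unique(groups)
    if len(uniq) < config.n_folds:
        raise ValueError("fewer cycles than folds")
    pred = np.empty(len(y), dtype=y.dtype)
    gkf = GroupKFold(n_splits=config.n_folds)
    for k, (tr, te) in enumerate(gkf.split(X, y, groups)):
        assert not set(groups[tr]) & set(groups[te]), "cycle leakage"
        model = RUSBoostClassifier(
            n_estimators=config.max_learners, learning_rate=config.learn_rate,
            max_splits=config.max_splits, random_state=config.seed + k)
        model.fit(X[tr], y[tr])
        pred[te] = model.predict(X[te])
    return summarize_predictions(y, pred, table, config, n_boot=n_boot)


def summarize_predictions(y: np.ndarray, pred: np.ndarray, table: pd.DataFrame,
                          config: DecoderConfig, n_boot: int = 1000) -> PerformanceReport:
    classes = np.unique(y)
    correct = pred == y
    per_class = pd.Series({c: float(correct[y == c].mean()) for c in classes})
    conf = pd.crosstab(pd.Series(y, name="true"), pd.Series(pred, name="pred"))
    rng = np.random.default_rng(config.seed)
    boots = np.array([correct[rng.integers(0, len(y), len(y))].mean()
                      for _ in range(n_boot)])
    lo, hi = np.percentile(boots, [2.5, 97.5])
    preds_df = table[["trial", "cycle_id"]].copy()
    preds_df["true"] = y
    preds_df["pred"] = pred
    preds_df["correct"] = correct
    return PerformanceReport(
        per_class=per_class, confusion=conf,
        overall=float(correct.mean()), class_mean=float(per_class.mean()),
        chance=1.0 / len(classes), ci_low=float(lo), ci_high=float(hi),
        n_per_class=pd.Series({c: int((y == c).sum()) for c in classes}),
        predictions=preds_df)


def conditional_performance(report: PerformanceReport, table: pd.DataFrame,
                            feature: str, n_quartiles: int = 4) -> pd.DataFrame:
    """Held-out correct fraction per quartile of a feature (or speed).

    Quartiles are labeled Q1 (lowest values) to Q4 (highest).  Empty cells are
    NaN-flagged rather than reported as zero.
    """
    values = table[feature].to_numpy(dtype=float)
    edges = np.percentile(values, np.linspace(0, 100, n_quartiles + 1))
    q = np.clip(np.searchsorted(edges[1:-1], values, side="left"), 0,
                n_quartiles - 1)
    correct = report.predictions["correct"].to_numpy()
    y = report.predictions["true"].to_numpy()
    rows = {}
    for k in range(n_quartiles):
        m = q == k
        row = {"n": int(m.sum()),
               "overall": float(correct[m].mean()) if m.any() else np.nan}
        for c in np.unique(y):
            mc = m & (y == c)
            row[c] = float(correct[mc].mean()) if mc.any() else np.nan
        rows[f"Q{k + 1}"] = row
    return pd.DataFrame(rows).T


def cross_classify(model: RUSBoostClassifier, table: pd.DataFrame) -> dict:
    """Direct (non-cross-validated) performance of a trained model on a table."""
    config: DecoderConfig = model.config
    if set(config.features) - set(table.columns):
        raise ValueError("feature-set mismatch between model and table")
    X = table[config.features].to_numpy(dtype=float)
    y = table[config.label_column].to_numpy()
    pred = model.predict(X)
    correct = pred == y
    per_class = {c: float(correct[y == c].mean()) for c in np.unique(y)}
    return {"overall": float(correct.mean()),
            "class_mean": float(np.mean(list(per_class.values()))),
            "per_class": per_class}


@dataclass
class TrialWindow:
    start: int
    stop: int           # inclusive trial index
    count: int


def make_learning_windows(per_trial_counts: pd.Series | dict,
                          target: int = 3000) -> list[TrialWindow]:
    """Consecutive-trial windows whose element counts are closest to ``target``.

    One window is proposed per start trial (stop chosen to minimize the
    distance of the cumulative count to ``target``); consecutive duplicates
    are removed.  When the total count is below ``target`` a single window
    spanning everything is returned.
    """
    counts = pd.Series(per_trial_counts).sort_index()
    trials = counts.index.to_numpy()
    vals = counts.to_numpy()
    if vals.sum() < target:
        return [TrialWindow(int(trials[0]), int(trials[-1]), int(vals.sum()))]
    windows: list[TrialWindow] = []
    for si in range(len(trials)):
        cum = np.cumsum(vals[si:])
        stop_rel = int(np.argmin(np.abs(cum - target)))
        w = TrialWindow(int(trials[si]), int(trials[si + stop_rel]),
                        int(cum[stop_rel]))
        if not windows or (w.start, w.stop) != (windows[-1].start, windows[-1].stop):
            windows.append(w)
    return windows


def early_late_split(per_trial_counts: pd.Series | dict) -> tuple[list[int], list[int]]:
    """Pivot trial balancing cumulative element counts between early and late."""
    counts = pd.Series(per_trial_counts).sort_index()
    vals = counts.to_numpy(dtype=float)
    total = vals.sum()
    cum = np.cumsum(vals)
    pivot = int(np.argmin(np.abs(cum - total / 2.0))) + 1
    trials = list(counts.index)
    return trials[:pivot], trials[pivot:]


def asymmetry_and_improvement(matrix: np.ndarray,
                              early_perf: float | None = None,
                              late_perf: float | None = None) -> dict:
    """Summaries of a cross-classification matrix.

    ``past_vs_future_pct`` is the relative percent difference between the
    means of the upper (train earlier, test later) and lower triangular parts.
    When early/late cross-validated performances are given,
    ``late_vs_early_pct`` is their relative percent difference.
    """
    m = np.asarray(matrix, dtype=float)
    if m.shape[0] != m.shape[1] or m.shape[0] < 2:
        raise ValueError("matrix must be square and at least 2x2")
    upper = m[np.triu_indices_from(m, k=1)]
    lower = m[np.tril_indices_from(m, k=-1)]
    out = {"past_vs_future_pct": 100.0 * (upper.mean() - lower.mean()) / lower.mean(),
           "upper_mean": float(upper.mean()), "lower_mean": float(lower.mean())}
    if early_perf is not None and late_perf is not None:
        out["late_vs_early_pct"] = 100.0 * (late_perf - early_perf) / early_perf
    return out


def block_means(matrix: np.ndarray, layer_by_trial: pd.DataFrame,
                layers: tuple[str, ...] = ("rad", "l-m"),
                min_fraction: float = 0.75) -> pd.DataFrame:
    """Layer-block averages of a channel cross-classification matrix.

    ``layer_by_trial`` is (n_channels, n_trials) of layer labels; a channel
    joins a layer block only when it carried that label in at least
    ``min_fraction`` of the trials.
    """
    m = np.asarray(matrix, dtype=float)
    membership = {}
    for layer in layers:
        frac = (layer_by_trial == layer).mean(axis=1)
        membership[layer] = np.nonzero(frac.to_numpy() >= min_fraction)[0]
    out = pd.DataFrame(index=layers, columns=layers, dtype=float)
    for la in layers:
        for lb in layers:
            ia, ib = membership[la], membership[lb]
            out.loc[la, lb] = (float(m[np.ix_(ia, ib)].mean())
                               if len(ia) and len(ib) else np.nan)
    return out
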