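"""Acidosis classification: base learners, abstaining ensemble, Pareto front.

Four base learners — SVM, random forest, a small feed-forward neural
network and a k-means classifier — are tuned by grid search under
5-fold cross-validation and combined into an *abstaining* ensemble: a
class is emitted only when every member agrees, otherwise the ensemble
answers "unsure".  Abstention trades coverage (number of samples
classified) against accuracy on the classified subset; the trade-off is
summarised by the two-objective Pareto front over all member
combinations.

The module also provides Gaussian-noise oversampling for small cohorts
and the stratified train/test split used throughout.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, cross_val_score, train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .io import ParameterError

UNSURE = "unsure"

__all__ = [
    "UNSURE",
    "LearnerSpec",
    "MetricsReport",
    "EnsembleDecision",
    "ComboEvaluation",
    "default_learner_specs",
    "train_learner",
    "fit_kmeans_classifier",
    "evaluate",
    "ensemble_predict",
    "evaluate_combinations",
    "pareto_front",
    "oversample_gaussian",
    "split_train_test",
    "AcidosisEnsemble",
    "EnsembleResults",
]


@dataclass(frozen=True)
class LearnerSpec:
    """A base learner kind plus its hyperparameter grid."""

    kind: str  # svm | random_forest | neural_net | kmeans
    grid: Mapping[str, Sequence] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("svm", "random_forest", "neural_net", "kmeans"):
            raise ParameterError(f"unknown learner kind {self.kind!r}")
        if self.kind != "kmeans" and not self.grid:
            raise ParameterError(f"{self.kind} requires a non-empty grid")


@dataclass
class MetricsReport:
    """Confusion-matrix metrics, as percentages in [0, 100].

    Undefined ratios (zero denominator) are NaN and listed in
    ``undefined`` rather than being silently zero-filled.
    """

    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    confusion: tuple[int, int, int, int]  # (TP, FP, TN, FN)
    undefined: tuple[str, ...] = ()

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "tp": self.confusion[0],
            "fp": self.confusion[1],
            "tn": self.confusion[2],
            "fn": self.confusion[3],
        }


@dataclass
class EnsembleDecision:
    """Per-learner votes plus the unanimous-or-unsure consensus."""

    per_learner: dict[str, int]
    consensus: int | str

    def __post_init__(self) -> None:
        votes = set(self.per_learner.values())
        expected = votes.pop() if len(votes) == 1 else UNSURE
        if self.consensus != expected:
            raise ParameterError("consensus inconsistent with per-learner votes")


@dataclass
class ComboEvaluation:
    """Coverage/accuracy of one ensemble membership on a test set."""

    combo: tuple[str, ...]
    n_classified: int
    accuracy_on_classified: float  # NaN when nothing was classified

    @property
    def name(self) -> str:
        return "/".join(self.combo)


def default_learner_specs(seed: int = 0) -> dict[str, LearnerSpec]:
    """The default grids for the four learners.

    SVM varies kernel, kernel width and margin penalty; the forest varies
    size and depth; the network varies hidden width, learning rate,
    activation and solver.  K-means has no supervised grid — it is
    restarted and the best inertia kept.
    """
    return {
        "SVM": LearnerSpec(
            "svm",
            {
                "kernel": ["linear", "rbf", "poly2", "poly3"],
                "gamma": [0.01, 0.1, 1.0],
                "C": [0.1, 1.0, 10.0],
            },
            seed,
        ),
        "RF": LearnerSpec(
            "random_forest",
            {"n_estimators": [50, 100, 200], "max_depth": [None, 3, 5]},
            seed,
        ),
        "NN": LearnerSpec(
            "neural_net",
            {
                "hidden": [4, 8, 16],
                "learning_rate": [0.001, 0.01],
                "activation": ["relu", "tanh"],
                "solver": ["lbfgs", "adam"],
            },
            seed,
        ),
        "Clu": LearnerSpec("kmeans", {}, seed),
    }


# ---------------------------------------------------------------------------
# learner construction
# ---------------------------------------------------------------------------


def _make_estimator(kind: str, point: Mapping, seed: int):
    """Instantiate one grid point; features are z-scored inside the
    pipeline so scaling is learned on training folds only."""
    if kind == "svm":
        kernel = point["kernel"]
        kw = dict(C=point["C"], gamma=point["gamma"], random_state=seed)
        if kernel.startswith("poly"):
            est = SVC(kernel="poly", degree=int(kernel[-1]), coef0=1.0, **kw)
        else:
            est = SVC(kernel=kernel, **kw)
    elif kind == "random_forest":
        est = RandomForestClassifier(
            n_estimators=point["n_estimators"],
            max_depth=point["max_depth"],
            random_state=seed,
        )
    elif kind == "neural_net":
        est = MLPClassifier(
            hidden_layer_sizes=(point["hidden"],),
            learning_rate_init=point["learning_rate"],
            activation=point["activation"],
            solver=point["solver"],
            max_iter=2000,
            random_state=seed,
        )
    else:
        raise ParameterError(f"no estimator for kind {kind!r}")
    return Pipeline([("scale", StandardScaler()), ("model", est)])


def _complexity(kind: str, point: Mapping) -> float:
    """Tie-break score: smaller is simpler."""
    if kind == "svm":
        kern_rank = {"linear": 0, "rbf": 1, "poly2": 2, "poly3": 3}
        return point["gamma"] * point["C"] + 0.001 * kern_rank[point["kernel"]]
    if kind == "random_forest":
        depth = point["max_depth"] or 100
        return point["n_estimators"] * depth
    if kind == "neural_net":
        return point["hidden"]
    return 0.0


def train_learner(
    spec: LearnerSpec,
    table: pd.DataFrame | np.ndarray,
    labels: Sequence[int],
    cv_folds: int = 5,
) -> tuple[object, MetricsReport, dict]:
    """Grid-search one learner under stratified 5-fold CV.

    The grid point with the best mean CV accuracy wins; ties go to the
    simpler model, then to grid order.  The winner is refit on the full
    training split.  Returns (fitted model, CV metrics at the selected
    point, selected hyperparameters).
    """
    X = np.asarray(table, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(X) != len(y):
        raise ParameterError("table and labels length mismatch")
    if len(X) < 10:
        raise ParameterError("need at least 10 training rows")
    if len(np.unique(y)) < 2:
        raise ParameterError("training labels contain a single class")
    if spec.kind == "kmeans":
        model = fit_kmeans_classifier(X, y, seed=spec.seed)
        preds = model.predict(X)
        return model, evaluate(preds, y), {}

    names = list(spec.grid)
    best = None  # (neg_acc, complexity, order, point)
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=spec.seed)
    for order, values in enumerate(itertools.product(*(spec.grid[n] for n in names))):
        point = dict(zip(names, values))
        est = _make_estimator(spec.kind, point, spec.seed)
        scores = cross_val_score(est, X, y, cv=cv, scoring="accuracy")
        key = (-scores.mean(), _complexity(spec.kind, point), order)
        if best is None or key < best[0]:
            best = (key, point, scores)
    point, scores = best[1], best[2]
    model = _make_estimator(spec.kind, point, spec.seed)
    model.fit(X, y)
    # CV metrics at the selected point, from out-of-fold predictions
    oof = np.empty_like(y)
    for tr, te in cv.split(X, y):
        est = _make_estimator(spec.kind, point, spec.seed)
        est.fit(X[tr], y[tr])
        oof[te] = est.predict(X[te])
    return model, evaluate(oof, y), point


class KMeansClassifier:
    """Unsupervised k-means with a majority-vote cluster-to-label map.

    Clusters are fit on the (z-scored) features only; each cluster takes
    the majority training label of its members, ties breaking toward
    class 1 (acidotic) — in monitoring a false alarm is safer than a
    miss.  Prediction is the mapped label of the nearest centroid.
    """

    def __init__(self, k: int = 2, seed: int = 0, n_restarts: int = 10):
        self.k, self.seed, self.n_restarts = k, seed, n_restarts

    def fit(self, X: np.ndarray, y: np.ndarray) -> "KMeansClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if len(np.unique(X, axis=0)) < self.k:
            raise ParameterError(
                f"fewer than k={self.k} distinct rows; k-means is degenerate"
            )
        self.scaler_ = StandardScaler().fit(X)
        Z = self.scaler_.transform(X)
        self.km_ = KMeans(
            n_clusters=self.k, n_init=self.n_restarts, random_state=self.seed
        ).fit(Z)
        assign = self.km_.labels_
        self.cluster_label_ = np.empty(self.k, dtype=int)
        for c in range(self.k):
            members = y[assign == c]
            if members.size == 0:
                self.cluster_label_[c] = 1
                continue
            ones, zeros = int((members == 1).sum()), int((members == 0).sum())
            self.cluster_label_[c] = 1 if ones >= zeros else 0
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        Z = self.scaler_.transform(np.asarray(X, dtype=float))
        return self.cluster_label_[self.km_.predict(Z)]


def fit_kmeans_classifier(
    table: pd.DataFrame | np.ndarray, labels: Sequence[int], k: int = 2, seed: int = 0
) -> KMeansClassifier:
    """Fit the k-means learner (see :class:`KMeansClassifier`)."""
    X = np.asarray(table, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(X) < k:
        raise ParameterError(f"need at least k={k} rows")
    return KMeansClassifier(k=k, seed=seed).fit(X, y)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def evaluate(
    preds: Sequence[int], labels: Sequence[int], positive_class: int = 1
) -> MetricsReport:
    """Accuracy, sensitivity, specificity and precision from a confusion
    matrix; percentages, with zero-denominator ratios flagged as NaN."""
    p = np.asarray(preds)
    y = np.asarray(labels)
    if p.shape != y.shape or p.size == 0:
        raise ParameterError("predictions and labels must be equal-length, nonempty")
    pos = positive_class
    tp = int(np.sum((p == pos) & (y == pos)))
    fp = int(np.sum((p == pos) & (y != pos)))
    tn = int(np.sum((p != pos) & (y != pos)))
    fn = int(np.sum((p != pos) & (y == pos)))
    undefined = []

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return float("nan")
        return 100.0 * num / den

    return MetricsReport(
        accuracy=ratio(tp + tn, tp + tn + fp + fn, "accuracy"),
        sensitivity=ratio(tp, tp + fn, "sensitivity"),
        specificity=ratio(tn, tn + fp, "specificity"),
        precision=ratio(tp, tp + fp, "precision"),
        confusion=(tp, fp, tn, fn),
        undefined=tuple(undefined),
    )


# ---------------------------------------------------------------------------
# abstaining ensemble
# ---------------------------------------------------------------------------


def ensemble_predict(
    models: Mapping[str, object], features: np.ndarray
) -> EnsembleDecision:
    """Unanimous vote over the member models for one feature vector.

    All members must agree for a class to be emitted; any disagreement
    yields ``"unsure"``.  The individual votes are always reported.
    """
    if len(models) < 2:
        raise ParameterError("an abstaining ensemble needs at least 2 models")
    x = np.asarray(features, dtype=float).reshape(1, -1)
    votes = {name: int(m.predict(x)[0]) for name, m in models.items()}
    vals = set(votes.values())
    consensus: int | str = vals.pop() if len(vals) == 1 else UNSURE
    return EnsembleDecision(per_learner=votes, consensus=consensus)


def _batch_votes(models: Mapping[str, object], X: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame({name: m.predict(X).astype(int) for name, m in models.items()})


def evaluate_combinations(
    models_by_name: Mapping[str, object],
    combos: Sequence[Sequence[str]],
    test_table: pd.DataFrame | np.ndarray,
    test_labels: Sequence[int],
) -> list[ComboEvaluation]:
    """Coverage and accuracy-on-classified for each ensemble membership."""
    X = np.asarray(test_table, dtype=float)
    y = np.asarray(test_labels, dtype=int)
    votes = _batch_votes(models_by_name, X)
    out = []
    for combo in combos:
        combo = tuple(combo)
        for name in combo:
            if name not in models_by_name:
                raise ParameterError(f"combo references unknown model {name!r}")
        sub = votes[list(combo)].to_numpy()
        unanimous = (sub == sub[:, :1]).all(axis=1)
        n_classified = int(unanimous.sum())
        if n_classified:
            acc = 100.0 * float(np.mean(sub[unanimous, 0] == y[unanimous]))
        else:
            acc = float("nan")
        out.append(ComboEvaluation(combo, n_classified, acc))
    return out


def all_combos(names: Sequence[str], min_size: int = 2) -> list[tuple[str, ...]]:
    """Every subset of the learner names of size >= ``min_size``."""
    return [
        c
        for r in range(min_size, len(names) + 1)
        for c in itertools.combinations(names, r)
    ]


def pareto_front(
    points: Sequence[tuple[float, float]]
) -> list[tuple[float, float]]:
    """Non-dominated subset of (n_classified, accuracy) points.

    A point is kept iff no other point is >= in both coordinates and
    strictly greater in at least one.  Returned in order of decreasing
    coverage.
    """
    pts = list(points)
    if not pts:
        raise ParameterError("pareto_front needs at least one point")
    front = [
        p
        for p in pts
        if not any(
            (q[0] >= p[0] and q[1] >= p[1]) and (q[0] > p[0] or q[1] > p[1])
            for q in pts
        )
    ]
    seen: set[tuple[float, float]] = set()
    unique = [p for p in front if not (p in seen or seen.add(p))]
    return sorted(unique, key=lambda p: (-p[0], -p[1]))


# ---------------------------------------------------------------------------
# oversampling and splits
# ---------------------------------------------------------------------------


def oversample_gaussian(
    table: pd.DataFrame,
    labels: Sequence[int],
    factor: float = 2.0,
    sigma_frac: float = 0.1,
    seed: int = 0,
    count_columns: Sequence[str] = (),
) -> tuple[pd.DataFrame, np.ndarray]:
    """Augment a feature table with Gaussian-jittered copies of its rows.

    Each synthetic row is a real row plus N(0, (sigma_frac * column sd)^2)
    noise per column, carrying its source row's label; count-valued
    columns are re-rounded and clipped at zero.  ``factor`` is the target
    size multiplier (2.0 doubles the table); originals come first.
    """
    if factor < 1:
        raise ParameterError("factor must be >= 1")
    if not (0 < sigma_frac <= 1):
        raise ParameterError("sigma_frac must lie in (0, 1]")
    y = np.asarray(labels, dtype=int)
    n_extra = int(round((factor - 1) * len(table)))
    if n_extra == 0:
        return table.copy(), y.copy()
    rng = np.random.default_rng(seed)
    num_cols = table.select_dtypes(include=[np.number]).columns
    sds = table[num_cols].std(ddof=0).to_numpy()
    # cycle through rows so class balance is preserved for integer factors
    src = np.tile(np.arange(len(table)), int(np.ceil(factor)))[: n_extra]
    new_rows = table.iloc[src].copy().reset_index(drop=True)
    noise = rng.normal(0.0, 1.0, size=(n_extra, len(num_cols))) * (sigma_frac * sds)
    new_rows[num_cols] = new_rows[num_cols].to_numpy() + noise
    for c in count_columns:
        if c in new_rows.columns:
            new_rows[c] = np.clip(np.round(new_rows[c]), 0, None).astype(int)
    aug = pd.concat([table.reset_index(drop=True), new_rows], ignore_index=True)
    return aug, np.concatenate([y, y[src]])


def split_train_test(
    table: pd.DataFrame,
    labels: Sequence[int],
    test_size: int = 24,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray, np.ndarray]:
    """Stratified train/test partition with a fixed test-set size."""
    y = np.asarray(labels, dtype=int)
    if not (0 < test_size < len(table)):
        raise ParameterError("test_size must lie strictly between 0 and n")
    Xtr, Xte, ytr, yte = train_test_split(
        table, y, test_size=test_size, stratify=y, random_state=seed
    )
    if len(np.unique(ytr)) < 2:
        raise ParameterError("split leaves a single class in training")
    return Xtr, Xte, ytr, yte


# ---------------------------------------------------------------------------
# statsmodels-style front end
# ---------------------------------------------------------------------------


class AcidosisEnsemble:
    """Abstaining-ensemble acidosis model over a feature table.

    Statsmodels-style front end: construct from data, ``fit()`` returns
    an :class:`EnsembleResults` carrying per-learner CV metrics, every
    combination's coverage/accuracy, and the Pareto front.

    Parameters
    ----------
    table : DataFrame
        Feature table (numeric feature columns only).
    labels : sequence of int
        0 = non-acidotic, 1 = acidotic.
    """

    def __init__(
        self,
        table: pd.DataFrame,
        labels: Sequence[int],
        specs: Mapping[str, LearnerSpec] | None = None,
        test_size: int = 24,
        seed: int = 0,
    ):
        self.table = table.reset_index(drop=True)
        self.labels = np.asarray(labels, dtype=int)
        self.specs = dict(specs) if specs is not None else default_learner_specs(seed)
        self.test_size = test_size
        self.seed = seed

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, label_column: str = "label", drop: Sequence[str] = ("record_id", "ph"), **kw
    ) -> "AcidosisEnsemble":
        labels = df[label_column].to_numpy(dtype=int)
        feats = df.drop(columns=[label_column, *[c for c in drop if c in df.columns]])
        return cls(feats, labels, **kw)

    def fit(self) -> "EnsembleResults":
        Xtr, Xte, ytr, yte = split_train_test(
            self.table, self.labels, self.test_size, self.seed
        )
        models: dict[str, object] = {}
        cv_metrics: dict[str, MetricsReport] = {}
        chosen: dict[str, dict] = {}
        for name, spec in self.specs.items():
            spec = LearnerSpec(spec.kind, spec.grid, self.seed)
            model, metrics, point = train_learner(spec, Xtr, ytr)
            models[name] = model
            cv_metrics[name] = metrics
            chosen[name] = point
        combos = all_combos(list(self.specs))
        evals = evaluate_combinations(models, combos, Xte, yte)
        front_pts = pareto_front(
            [(e.n_classified, e.accuracy_on_classified) for e in evals if e.n_classified]
        )
        front = [
            e
            for e in evals
            if (e.n_classified, e.accuracy_on_classified) in front_pts
        ]
        test_metrics = {
            name: evaluate(m.predict(np.asarray(Xte, dtype=float)), yte)
            for name, m in models.items()
        }
        return EnsembleResults(
            model=self,
            models=models,
            selected_hyperparameters=chosen,
            cv_metrics=cv_metrics,
            test_metrics=test_metrics,
            combo_evaluations=evals,
            pareto=front,
            split=(Xtr, Xte, ytr, yte),
        )


@dataclass
class EnsembleResults:
    """Fitted learners, their metrics, and the coverage/accuracy front."""

    model: AcidosisEnsemble
    models: dict[str, object]
    selected_hyperparameters: dict[str, dict]
    cv_metrics: dict[str, MetricsReport]
    test_metrics: dict[str, MetricsReport]
    combo_evaluations: list[ComboEvaluation]
    pareto: list[ComboEvaluation]
    split: tuple

    def predict(self, features: np.ndarray, members: Sequence[str] = ("RF", "NN")) -> EnsembleDecision:
        """Abstaining prediction for one feature vector using ``members``."""
        return ensemble_predict({m: self.models[m] for m in members}, features)

    def combo(self, *names: str) -> ComboEvaluation:
        target = tuple(names)
        for e in self.combo_evaluations:
            if set(e.combo) == set(target):
                return e
        raise KeyError(f"combination {target} was not evaluated")

    def summary(self) -> str:
        lines = ["Abstaining acidosis ensemble", "=" * 60]
        lines.append(f"{'learner':<8}{'CV acc':>8}{'test acc':>10}  selected")
        for name in self.models:
            cv = self.cv_metrics[name].accuracy
            te = self.test_metrics[name].accuracy
            lines.append(
                f"{name:<8}{cv:>8.2f}{te:>10.2f}  {self.selected_hyperparameters[name]}"
            )
        lines.append("-" * 60)
        lines.append(f"{'combination':<18}{'classified':>11}{'accuracy':>10}{'front':>7}")
        front_set = {tuple(e.combo) for e in self.pareto}
        for e in sorted(self.combo_evaluations, key=lambda e: -e.n_classified):
            mark = "*" if tuple(e.combo) in front_set else ""
            acc = f"{e.accuracy_on_classified:.2f}" if np.isfinite(
                e.accuracy_on_classified
            ) else "undef"
            lines.append(f"{e.name:<18}{e.n_classified:>11}{acc:>10}{mark:>7}")
        return "\n".join(lines)
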