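"""Elastic-net scoring for cancer detection and tissue of origin.

A penalized logistic model maps the per-sample feature vector
(fragmentomics FDD summaries, optionally plus the three cfMeDIP features)
to a detection score in [0, 1]. The penalty mixes L1 and L2 with mixing
parameter α (default 0.5); the regularization strength λ is chosen from a
small grid (0 to 0.05 in steps of 0.01) by 10-fold cross-validated
binomial deviance, ties broken toward stronger regularization. λ follows
the glmnet parameterization

    (1/n) Σ loss + λ [ α‖β‖₁ + (1−α)/2 ‖β‖₂² ]

and is mapped internally onto scikit-learn's ``C = 1/(n·λ)``.

Within-cohort performance uses repeated stratified cross-validation
(default 100 repetitions of 10 folds): each sample is scored once per
repetition while held out, scores are averaged across repetitions, and
AUC plus sensitivity/specificity at the Youden-optimal threshold are
reported on the averaged scores. Cross-cohort training can first restrict
to confidently labeled samples (tumors with tumor fraction above 0.03,
healthy below 0.01, strict inequalities).

Tissue-of-origin classification concatenates each cancer type's
region-specific feature block into one matrix and fits a multinomial
elastic net, evaluated one-vs-rest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, softmax
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import LeaveOneOut, StratifiedKFold

logger = logging.getLogger(__name__)

STAGE_CODES = {"H": 0, "I": 1, "II": 2, "III": 3, "IV": 4}


@dataclass
class FeatureMatrix:
    """Assembled per-sample features with labels and optional metadata.

    ``features`` is a samples × named-features DataFrame with no missing
    values; ``labels`` aligns with its index. ``tf`` (tumor fraction) and
    ``stage`` are optional per-sample metadata used by the training filter
    and the stage-correlation analysis.
    """

    features: pd.DataFrame
    labels: pd.Series
    cohort: str = "NA"
    tf: pd.Series | None = None
    stage: pd.Series | None = None

    def __post_init__(self) -> None:
        self.labels = pd.Series(self.labels, index=self.features.index)
        if self.features.isna().any().any():
            bad = self.features.columns[self.features.isna().any()].tolist()
            raise ValueError(f"missing feature values in columns {bad}")
        if self.tf is not None:
            self.tf = pd.Series(self.tf, index=self.features.index)
        if self.stage is not None:
            self.stage = pd.Series(self.stage, index=self.features.index)

    @property
    def samples(self) -> list[str]:
        return list(self.features.index)

    def subset(self, keep: pd.Index | Sequence[str]) -> "FeatureMatrix":
        return FeatureMatrix(
            features=self.features.loc[keep],
            labels=self.labels.loc[keep],
            cohort=self.cohort,
            tf=None if self.tf is None else self.tf.loc[keep],
            stage=None if self.stage is None else self.stage.loc[keep],
        )


@dataclass
class ElasticNetSpec:
    """Model hyperparameters and the cross-validation protocol."""

    alpha: float = 0.5
    lambda_grid: tuple[float, ...] = (0.0, 0.01, 0.02, 0.03, 0.04, 0.05)
    n_folds: int = 10
    n_repeats: int = 100
    seed: int = 0
    standardize: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha must be in [0,1]")
        if not self.lambda_grid or any(l < 0 for l in self.lambda_grid):
            raise ValueError("lambda_grid must be nonempty and nonnegative")


@dataclass
class TrainedScorer:
    """A fitted elastic-net scorer, self-contained for scoring.

    Stores coefficients on the standardized scale together with the
    feature means/scales used, so scoring new samples needs nothing else.
    For the binary model ``classes`` is [negative, positive] and the score
    is P(positive); for multinomial, one coefficient row per class.
    """

    kind: str  # "binary" | "multinomial"
    feature_names: list[str]
    classes: list[str]
    coef: np.ndarray  # (n_features,) binary, (n_classes, n_features) multinomial
    intercept: np.ndarray  # scalar-like (1,) or (n_classes,)
    chosen_lambda: float
    means: np.ndarray
    scales: np.ndarray
    metadata: dict = field(default_factory=dict)

    def _standardize(self, x: np.ndarray) -> np.ndarray:
        return (x - self.means) / self.scales

    def _check_schema(self, features: pd.DataFrame) -> pd.DataFrame:
        missing = [c for c in self.feature_names if c not in features.columns]
        extra = [c for c in features.columns if c not in self.feature_names]
        if missing:
            raise ValueError(f"schema mismatch: missing features {missing}, extra {extra}")
        return features[self.feature_names]

    def score(self, features: pd.DataFrame | dict[str, float]) -> np.ndarray:
        """Detection score(s) in [0,1] (binary) for sample rows."""
        if isinstance(features, dict):
            features = pd.DataFrame([features])
        x = self._standardize(self._check_schema(features).to_numpy(dtype=float))
        if self.kind == "binary":
            return expit(x @ self.coef + self.intercept[0])
        raise ValueError("score() is for binary models; use predict_proba()")

    def predict_proba(self, features: pd.DataFrame) -> pd.DataFrame:
        """Per-class probabilities (softmax) for a multinomial model."""
        if self.kind != "multinomial":
            p = self.score(features)
            return pd.DataFrame(
                {self.classes[0]: 1 - p, self.classes[1]: p}, index=features.index
            )
        x = self._standardize(self._check_schema(features).to_numpy(dtype=float))
        logits = x @ self.coef.T + self.intercept
        return pd.DataFrame(softmax(logits, axis=1), columns=self.classes, index=features.index)

    # --- JSON serialization (portable, diffable) ---
    def to_json(self, path: str | Path) -> None:
        payload = {
            "kind": self.kind,
            "feature_names": self.feature_names,
            "classes": self.classes,
            "coef": self.coef.tolist(),
            "intercept": self.intercept.tolist(),
            "chosen_lambda": self.chosen_lambda,
            "means": self.means.tolist(),
            "scales": self.scales.tolist(),
            "metadata": self.metadata,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "TrainedScorer":
        payload = json.loads(Path(path).read_text())
        return cls(
            kind=payload["kind"],
            feature_names=payload["feature_names"],
            classes=payload["classes"],
            coef=np.asarray(payload["coef"]),
            intercept=np.asarray(payload["intercept"]),
            chosen_lambda=payload["chosen_lambda"],
            means=np.asarray(payload["means"]),
            scales=np.asarray(payload["scales"]),
            metadata=payload["metadata"],
        )


# --- fitting internals -----------------------------------------------------

def _sk_model(alpha: float, lam: float, n: int, multinomial: bool) -> LogisticRegression:
    if lam == 0.0:
        return LogisticRegression(C=np.inf, solver="lbfgs", max_iter=10000, tol=1e-8)
    return LogisticRegression(
        solver="saga",
        l1_ratio=alpha,
        C=1.0 / (lam * n),
        max_iter=20000,
        tol=1e-7,
        random_state=0,  # saga shuffles; pin for bit-reproducibility
    )


def _standardize_train(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    means = X.mean(axis=0)
    scales = X.std(axis=0, ddof=0)
    scales = np.where(scales == 0, 1.0, scales)  # constant-within-fold guard
    return (X - means) / scales, means, scales


def _binomial_deviance(y01: np.ndarray, p: np.ndarray) -> float:
    eps = 1e-12
    p = np.clip(p, eps, 1 - eps)
    return float(-2.0 * np.mean(y01 * np.log(p) + (1 - y01) * np.log(1 - p)))


def _cv_splitter(y: np.ndarray, n_folds: int, seed: int):
    """Stratified K folds; tiny classes fall back to leave-one-out."""
    min_class = int(np.bincount(y).min())
    if min_class >= 2:
        return StratifiedKFold(
            n_splits=min(n_folds, min_class), shuffle=True, random_state=seed
        )
    logger.warning("class with a single sample: falling back to leave-one-out CV")
    return LeaveOneOut()


def _select_lambda(
    X: np.ndarray, y01: np.ndarray, spec: ElasticNetSpec, multinomial: bool = False
) -> float:
    """Grid CV on mean held-out deviance; ties go to the larger λ."""
    splitter = _cv_splitter(y01, spec.n_folds, spec.seed)
    folds = list(splitter.split(X, y01))
    mean_dev = {}
    for lam in spec.lambda_grid:
        devs = []
        for tr, te in folds:
            Xtr, means, scales = _standardize_train(X[tr])
            Xte = (X[te] - means) / scales
            clf = _sk_model(spec.alpha, lam, len(tr), multinomial)
            clf.fit(Xtr, y01[tr])
            proba = clf.predict_proba(Xte)
            if multinomial:
                eps = 1e-12
                rowp = np.clip(proba[np.arange(len(te)), y01[te]], eps, 1.0)
                devs.append(float(-2.0 * np.mean(np.log(rowp))))
            else:
                devs.append(_binomial_deviance(y01[te], proba[:, 1]))
        mean_dev[lam] = float(np.mean(devs))
    best = min(mean_dev.values())
    # ties (within numerical fuzz) resolved toward stronger regularization
    return max(l for l, d in mean_dev.items() if d <= best + 1e-10)


def _prepare(matrix: FeatureMatrix) -> tuple[np.ndarray, list[str]]:
    X = matrix.features.to_numpy(dtype=float)
    names = list(matrix.features.columns)
    keep = X.std(axis=0) > 0
    if not keep.all():
        dropped = [n for n, k in zip(names, keep) if not k]
        logger.warning("dropping constant features: %s", dropped)
        X = X[:, keep]
        names = [n for n, k in zip(names, keep) if k]
    if not names:
        raise ValueError("no non-constant features to train on")
    return X, names


def train(matrix: FeatureMatrix, spec: ElasticNetSpec | None = None) -> TrainedScorer:
    """Fit the binary elastic-net scorer with CV-chosen λ.

    Features are standardized with training-set mean/sd (stored on the
    scorer); λ comes from :func:`_select_lambda`; the final model is
    refit on all rows at the chosen λ. The positive class is "cancer"
    when present, otherwise the lexicographically larger label.
    """
    spec = spec or ElasticNetSpec()
    classes = sorted(matrix.labels.unique())
    if len(classes) != 2:
        raise ValueError(f"binary training needs exactly 2 classes, got {classes}")
    if "cancer" in classes:  # cancer is always the positive class
        classes = [c for c in classes if c != "cancer"] + ["cancer"]
    X, names = _prepare(matrix)
    y01 = (matrix.labels.to_numpy() == classes[1]).astype(int)
    lam = _select_lambda(X, y01, spec)
    Xs, means, scales = _standardize_train(X)
    clf = _sk_model(spec.alpha, lam, len(y01), multinomial=False)
    clf.fit(Xs, y01)
    return TrainedScorer(
        kind="binary",
        feature_names=names,
        classes=[str(c) for c in classes],
        coef=clf.coef_[0].copy(),
        intercept=clf.intercept_.copy(),
        chosen_lambda=lam,
        means=means,
        scales=scales,
        metadata={
            "cohort": matrix.cohort,
            "alpha": spec.alpha,
            "seed": spec.seed,
            "n_samples": int(len(y01)),
        },
    )


@dataclass
class CvResult:
    """Repeated-CV output: averaged out-of-fold scores and summary metrics."""

    scores: pd.Series  # mean out-of-fold score per sample
    labels: pd.Series
    auc: float
    threshold: float  # Youden-optimal on the averaged scores
    sensitivity: float
    specificity: float
    chosen_lambda: float


def repeated_cv(matrix: FeatureMatrix, spec: ElasticNetSpec | None = None) -> CvResult:
    """Repeated stratified K-fold CV scores and metrics.

    λ is selected once on the full matrix by CV deviance; each of the
    ``n_repeats`` repetitions then reassigns stratified folds with seed
    ``seed + r`` and scores every sample exactly once while held out
    (per-fold standardization). The final per-sample score is the mean
    over repetitions; AUC and the Youden-threshold sensitivity/specificity
    are computed on those averaged scores.
    """
    spec = spec or ElasticNetSpec()
    classes = sorted(matrix.labels.unique())
    if len(classes) != 2:
        raise ValueError(f"binary CV needs exactly 2 classes, got {classes}")
    if "cancer" in classes:
        classes = [c for c in classes if c != "cancer"] + ["cancer"]
    X, _ = _prepare(matrix)
    y01 = (matrix.labels.to_numpy() == classes[1]).astype(int)
    lam = _select_lambda(X, y01, spec)
    n = len(y01)
    score_sum = np.zeros(n)
    for r in range(spec.n_repeats):
        splitter = _cv_splitter(y01, spec.n_folds, spec.seed + r)
        for tr, te in splitter.split(X, y01):
            Xtr, means, scales = _standardize_train(X[tr])
            clf = _sk_model(spec.alpha, lam, len(tr), multinomial=False)
            clf.fit(Xtr, y01[tr])
            score_sum[te] += clf.predict_proba((X[te] - means) / scales)[:, 1]
    mean_scores = score_sum / spec.n_repeats
    auc = float(roc_auc_score(y01, mean_scores))
    fpr, tpr, thr = roc_curve(y01, mean_scores)
    youden = int(np.argmax(tpr - fpr))
    return CvResult(
        scores=pd.Series(mean_scores, index=matrix.features.index, name="score"),
        labels=matrix.labels.copy(),
        auc=auc,
        threshold=float(thr[youden]),
        sensitivity=float(tpr[youden]),
        specificity=float(1 - fpr[youden]),
        chosen_lambda=lam,
    )


def apply_training_filters(
    matrix: FeatureMatrix, tumor_tf_min: float = 0.03, healthy_tf_max: float = 0.01
) -> FeatureMatrix:
    """Keep tumors with TF strictly above ``tumor_tf_min`` and healthy
    controls with TF strictly below ``healthy_tf_max``.

    Boundary values are excluded on both rules. Used before cross-cohort
    training so the model learns from confidently labeled samples.
    """
    if matrix.tf is None:
        raise ValueError("tf column required for training filters")
    is_cancer = matrix.labels == "cancer"
    keep = (is_cancer & (matrix.tf > tumor_tf_min)) | (
        ~is_cancer & (matrix.tf < healthy_tf_max)
    )
    dropped = matrix.features.index[~keep].tolist()
    if dropped:
        logger.info("training filter dropped %d samples: %s", len(dropped), dropped)
    filtered = matrix.subset(matrix.features.index[keep])
    counts = filtered.labels.value_counts()
    if len(counts) < 2 or (counts < 1).any():
        raise ValueError("training filter emptied a class")
    return filtered


@dataclass
class TooResult:
    """Tissue-of-origin CV output: per-class one-vs-rest AUCs and scores."""

    scorer: TrainedScorer
    class_scores: pd.DataFrame  # mean out-of-fold probability per class
    class_auc: dict[str, float]
    predicted: pd.Series


def train_too(matrix: FeatureMatrix, spec: ElasticNetSpec | None = None) -> TooResult:
    """Multinomial elastic net over concatenated per-cancer-type blocks.

    Each sample must carry features computed against EVERY cancer type's
    region sets (the FeatureMatrix constructor already rejects missing
    values, so an absent block surfaces as an error at assembly). One-vs-
    rest AUC per class is computed from repeated-CV averaged class
    probabilities.
    """
    spec = spec or ElasticNetSpec()
    classes = sorted(matrix.labels.unique())
    if len(classes) < 2:
        raise ValueError("tissue-of-origin training needs at least 2 classes")
    X, names = _prepare(matrix)
    class_index = {c: i for i, c in enumerate(classes)}
    y = np.array([class_index[l] for l in matrix.labels])
    lam = _select_lambda(X, y, spec, multinomial=True)

    Xs, means, scales = _standardize_train(X)
    clf = _sk_model(spec.alpha, lam, len(y), multinomial=True)
    clf.fit(Xs, y)
    coef = clf.coef_
    intercept = clf.intercept_
    if coef.shape[0] == 1 and len(classes) == 2:  # sklearn collapses binary
        coef = np.vstack([-coef[0], coef[0]]) / 2.0
        intercept = np.array([-intercept[0], intercept[0]]) / 2.0
    scorer = TrainedScorer(
        kind="multinomial",
        feature_names=names,
        classes=[str(c) for c in classes],
        coef=coef,
        intercept=intercept,
        chosen_lambda=lam,
        means=means,
        scales=scales,
        metadata={"cohort": matrix.cohort, "alpha": spec.alpha, "seed": spec.seed},
    )

    proba_sum = np.zeros((len(y), len(classes)))
    for r in range(spec.n_repeats):
        splitter = _cv_splitter(y, spec.n_folds, spec.seed + r)
        for tr, te in splitter.split(X, y):
            Xtr, m, s = _standardize_train(X[tr])
            fold_clf = _sk_model(spec.alpha, lam, len(tr), multinomial=True)
            fold_clf.fit(Xtr, y[tr])
            proba = fold_clf.predict_proba((X[te] - m) / s)
            # fold may miss a class entirely; map columns by fitted classes
            cols = np.asarray(fold_clf.classes_, dtype=int)
            proba_sum[np.ix_(te, cols)] += proba
    mean_proba = proba_sum / spec.n_repeats
    mean_proba = mean_proba / mean_proba.sum(axis=1, keepdims=True)
    class_scores = pd.DataFrame(
        mean_proba, columns=[str(c) for c in classes], index=matrix.features.index
    )
    class_auc = {
        str(c): float(roc_auc_score((y == i).astype(int), mean_proba[:, i]))
        for c, i in class_index.items()
    }
    predicted = pd.Series(
        [str(classes[i]) for i in mean_proba.argmax(axis=1)],
        index=matrix.features.index,
        name="predicted",
    )
    return TooResult(
        scorer=scorer, class_scores=class_scores, class_auc=class_auc, predicted=predicted
    )


def delta_score(scores_tumor: Sequence[float], scores_control: Sequence[float]) -> float:
    """Mean tumor score minus mean control score — class separation on the
    score scale, interpretable where AUC only ranks."""
    if len(scores_tumor) == 0 or len(scores_control) == 0:
        raise ValueError("both score lists must be nonempty")
    return float(np.mean(scores_tumor) - np.mean(scores_control))


def stage_correlation(
    scores: Sequence[float], stages: Sequence[str | int]
) -> tuple[float, float]:
    """Pearson correlation of detection score vs. ordinal cancer stage.

    Stages are encoded H=0, I=1, II=2, III=3, IV=4 (integers pass
    through). Returns (r, two-sided p).
    """
    codes = np.array(
        [STAGE_CODES[s] if isinstance(s, str) else int(s) for s in stages], dtype=float
    )
    scores = np.asarray(scores, dtype=float)
    if len(scores) < 3:
        raise ValueError("need at least 3 samples with stage")
    if np.std(scores) == 0 or np.std(codes) == 0 or len(np.unique(codes)) < 2:
        raise ValueError("degenerate correlation: constant scores or stages")
    r, p = stats.pearsonr(scores, codes)
    return float(r), float(p)


# --- feature table I/O ------------------------------------------------------

def read_feature_matrix(
    features_path: str | Path, meta_path: str | Path | None = None, cohort: str = "NA"
) -> FeatureMatrix:
    """Read a features TSV (sample_id + named columns) and optional metadata
    TSV (sample_id, label, and optional tf / stage columns)."""
    feats = pd.read_csv(features_path, sep="\t").set_index("sample_id")
    if meta_path is None:
        raise ValueError("metadata TSV with labels is required for training")
    meta = pd.read_csv(meta_path, sep="\t").set_index("sample_id")
    if "label" not in meta.columns:
        raise ValueError("metadata TSV needs a 'label' column")
    meta = meta.loc[feats.index]
    return FeatureMatrix(
        features=feats,
        labels=meta["label"],
        cohort=cohort,
        tf=meta["tf"] if "tf" in meta.columns else None,
        stage=meta["stage"] if "stage" in meta.columns else None,
    )


def write_feature_matrix(matrix: FeatureMatrix, path: str | Path) -> None:
    out = matrix.features.copy()
    out.insert(0, "sample_id", out.index)
    out.to_csv(path, sep="\t", index=False)
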