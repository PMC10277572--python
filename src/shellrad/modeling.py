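"""Model training and evaluation for the nine partition strategies.

The cohort is split 8:2 (stratified) into training and test sets; each
strategy's features pass through LASSO selection on the training cohort,
an RBF support-vector classifier with probability calibration is fit with
10-fold stratified cross-validation, and the refit model is evaluated on
the held-out test cohort: ROC/AUC with a DeLong 95% CI, a Youden-optimal
cutoff chosen on the training CV predictions, the confusion matrix and
derived metrics at that cutoff, pairwise DeLong tests between strategies,
and decision-curve analysis for the fusion/integration models.

The positive class is "response" (label 1) throughout, so sensitivity is
response-group recall.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold, cross_val_predict
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features_dl import ConvBackbone, extract_deep
from .features_hc import HCConfig, extract_handcrafted
from .fusion_select import (
    STRATEGIES,
    FeatureMatrix,
    SelectionResult,
    fuse_features,
    integrate,
    lasso_select,
)
from .partition import ShellSpec, interval_tag, make_shell_mask, make_sphere_mask
from .polar import DEFAULT_HU_WINDOW, replicate_channels, rotational_slices
from .volume_io import Volume, resample_isotropic

logger = logging.getLogger(__name__)

__all__ = [
    "SplitPlan",
    "ConfusionMatrix",
    "MetricsReport",
    "ROCReport",
    "DelongResult",
    "DCACurve",
    "TrainedModel",
    "ModelReport",
    "NineModelConfig",
    "NineModelResult",
    "make_split",
    "train_svm",
    "metrics_from_confusion",
    "confusion_from_scores",
    "roc_auc",
    "delong_test",
    "dca_curve",
    "select_cutoff",
    "run_nine_models",
]

FUSION_STRATEGIES = (
    "feature_fusion",
    "image_fusion",
    "feature_fusion_integration",
    "image_fusion_integration",
)


def _round2(x: float) -> float:
    """Round half-up to 2 decimals (reporting convention)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), ROUND_HALF_UP))


# ------------------------------------------------------------------ split

@dataclass
class SplitPlan:
    """A stratified train/test split of the cohort."""

    train_ids: list[str]
    test_ids: list[str]
    ratio: float
    seed: int

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test sets overlap")


def make_split(labels: pd.Series, ratio: float = 0.2, seed: int = 0) -> SplitPlan:
    """Stratified split with largest-remainder rounding of per-class counts.

    ``labels`` is a 0/1 Series indexed by patient id.  The total test size
    is ``round(n * ratio)``, apportioned between classes by largest
    remainder so class proportions are preserved within one subject.
    """
    if not 0 < ratio < 1:
        raise ValueError(f"split ratio must be in (0, 1), got {ratio}")
    y = labels.astype(int)
    counts = y.value_counts()
    if len(counts) < 2 or counts.min() < 10:
        raise ValueError("need at least 10 subjects per class to split")
    n_test = int(round(len(y) * ratio))
    raw = {c: counts[c] * ratio for c in counts.index}
    base = {c: int(np.floor(raw[c])) for c in counts.index}
    short = n_test - sum(base.values())
    for c in sorted(counts.index, key=lambda c: raw[c] - base[c], reverse=True)[:short]:
        base[c] += 1
    rng = np.random.default_rng(seed)
    test_ids: list[str] = []
    for c in sorted(counts.index):
        ids = np.asarray(y.index[y == c])
        test_ids.extend(rng.permutation(ids)[: base[c]].tolist())
    test_set = set(test_ids)
    train_ids = [i for i in y.index if i not in test_set]
    return SplitPlan(train_ids, sorted(test_ids, key=list(y.index).index), ratio, seed)


# ------------------------------------------------------------ confusion

@dataclass
class ConfusionMatrix:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


def confusion_from_scores(scores, labels, cutoff: float) -> ConfusionMatrix:
    """Count outcomes with predicted-positive defined as score >= cutoff."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    pred = s >= cutoff
    return ConfusionMatrix(
        tp=int(np.sum(pred & (y == 1))),
        fn=int(np.sum(~pred & (y == 1))),
        tn=int(np.sum(~pred & (y == 0))),
        fp=int(np.sum(pred & (y == 0))),
    )


@dataclass
class MetricsReport:
    """Closed-form metrics of a confusion matrix (unrounded)."""

    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    cutoff: float = float("nan")

    def rounded(self) -> dict[str, float]:
        """Metrics rounded half-up to 2 decimals for reporting."""
        return {
            "accuracy": _round2(self.accuracy),
            "sensitivity": _round2(self.sensitivity),
            "specificity": _round2(self.specificity),
            "precision": _round2(self.precision),
            "f1": _round2(self.f1),
        }


def metrics_from_confusion(cm: ConfusionMatrix, cutoff: float = float("nan")) -> MetricsReport:
    if cm.total == 0:
        raise ValueError("confusion matrix is all zero")
    pos = cm.tp + cm.fn
    neg = cm.tn + cm.fp
    sens = cm.tp / pos if pos else 0.0
    spec = cm.tn / neg if neg else 0.0
    if cm.tp + cm.fp == 0:
        warnings.warn("no predicted positives; precision reported as 0")
        prec = 0.0
    else:
        prec = cm.tp / (cm.tp + cm.fp)
    f1 = 2 * prec * sens / (prec + sens) if (prec + sens) > 0 else 0.0
    return MetricsReport(
        accuracy=(cm.tp + cm.tn) / cm.total,
        sensitivity=sens,
        specificity=spec,
        precision=prec,
        f1=f1,
        cutoff=cutoff,
    )


# ------------------------------------------------------------------- ROC

def _midrank_components(scores: np.ndarray, labels: np.ndarray):
    """DeLong structural components V10 (per positive) and V01 (per negative)."""
    x = scores[labels == 1]
    yneg = scores[labels == 0]
    m, n = x.size, yneg.size
    allr = stats.rankdata(np.concatenate([x, yneg]))
    rx = stats.rankdata(x)
    ry = stats.rankdata(yneg)
    v10 = (allr[:m] - rx) / n
    v01 = 1.0 - (allr[m:] - ry) / m
    auc = (allr[:m].sum() - m * (m + 1) / 2) / (m * n)
    return auc, v10, v01


@dataclass
class ROCReport:
    """ROC curve with Mann–Whitney AUC and DeLong 95% CI."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray  # candidate cutoffs (ascending), midpoints
    auc: float
    ci95: tuple[float, float]
    n_pos: int
    n_neg: int


def roc_auc(scores, labels) -> ROCReport:
    """ROC and AUC (midrank Mann–Whitney) with a DeLong normal-theory CI."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape:
        raise ValueError("scores and labels differ in length")
    m = int(np.sum(y == 1))
    n = int(np.sum(y == 0))
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    auc, v10, v01 = _midrank_components(s, y)
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (
        np.var(v01, ddof=1) / n if n > 1 else 0.0
    )
    half = stats.norm.ppf(0.975) * np.sqrt(max(var, 0.0))
    ci = (float(np.clip(auc - half, 0, 1)), float(np.clip(auc + half, 0, 1)))

    uniq = np.unique(s)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    thresholds = np.concatenate(([uniq[0] - 1.0], mids, [uniq[-1] + 1.0]))
    pred = s[None, :] >= thresholds[:, None]
    tpr = (pred & (y == 1)).sum(axis=1) / m
    fpr = (pred & (y == 0)).sum(axis=1) / n
    return ROCReport(fpr, tpr, thresholds, float(auc), ci, m, n)


def select_cutoff(roc: ROCReport) -> float:
    """Threshold maximizing Youden's J; ties break toward the lower threshold."""
    j = roc.tpr - roc.fpr
    return float(roc.thresholds[int(np.argmax(j))])


# ---------------------------------------------------------------- DeLong

@dataclass
class DelongResult:
    auc_a: float
    auc_b: float
    var_a: float
    var_b: float
    cov_ab: float
    z: float
    p: float


def delong_test(scores_a, scores_b, labels) -> DelongResult:
    """Paired DeLong test for two correlated AUCs on the same subjects."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels, dtype=int)
    if a.shape != b.shape or a.shape != y.shape:
        raise ValueError("score vectors and labels must cover the same subjects")
    m = int(np.sum(y == 1))
    n = int(np.sum(y == 0))
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    auc_a, v10a, v01a = _midrank_components(a, y)
    auc_b, v10b, v01b = _midrank_components(b, y)
    s10 = np.cov(np.stack([v10a, v10b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.stack([v01a, v01b]), ddof=1) if n > 1 else np.zeros((2, 2))
    s = s10 / m + s01 / n
    var_diff = s[0, 0] + s[1, 1] - 2 * s[0, 1]
    diff = auc_a - auc_b
    if var_diff <= 1e-16:
        z = 0.0
        p = 1.0 if abs(diff) < 1e-12 else 0.0
    else:
        z = diff / np.sqrt(var_diff)
        p = 2.0 * stats.norm.sf(abs(z))
    return DelongResult(
        float(auc_a), float(auc_b), float(s[0, 0]), float(s[1, 1]),
        float(s[0, 1]), float(z), float(p),
    )


# ------------------------------------------------------------------- DCA

@dataclass
class DCACurve:
    thresholds: np.ndarray  # p_t grid in (0, 1)
    net_benefit: np.ndarray
    treat_all: np.ndarray
    treat_none: np.ndarray
    prevalence: float


def dca_curve(scores, labels, grid: np.ndarray | None = None) -> DCACurve:
    """Decision-curve analysis: net benefit over threshold probabilities.

    Net benefit at p_t = TP/n − FP/n · p_t/(1−p_t), with predicted positive
    defined as score ≥ p_t.  Treat-all classifies everyone positive;
    treat-none is identically zero.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if grid is None:
        grid = np.linspace(0.01, 0.99, 99)
    grid = np.asarray(grid, dtype=float)
    if np.any((grid <= 0) | (grid >= 1)):
        raise ValueError("threshold probabilities must lie strictly in (0, 1)")
    n = y.size
    prevalence = float(np.mean(y == 1))
    odds = grid / (1.0 - grid)
    pred = s[None, :] >= grid[:, None]
    tp = (pred & (y == 1)).sum(axis=1)
    fp = (pred & (y == 0)).sum(axis=1)
    nb = tp / n - fp / n * odds
    treat_all = prevalence - (1.0 - prevalence) * odds
    return DCACurve(grid, nb, treat_all, np.zeros_like(grid), prevalence)


# ------------------------------------------------------------------- SVM

@dataclass
class TrainedModel:
    """A fit SVM pipeline plus its training-cohort CV predictions."""

    model: Pipeline
    feature_names: list[str]
    cv_scores: np.ndarray  # out-of-fold response probability per training subject
    cv_auc: float
    seed: int

    def predict_scores(self, x: pd.DataFrame) -> np.ndarray:
        return self.model.predict_proba(x.to_numpy(dtype=float))[:, 1]


def train_svm(x: pd.DataFrame, y, folds: int = 10, seed: int = 0) -> TrainedModel:
    """Fit an RBF SVM (C=1, gamma='scale') with probability calibration.

    Features are z-scored with training statistics inside the pipeline.
    Out-of-fold probabilities from seeded stratified ``folds``-fold CV on
    the training cohort are kept for cutoff selection and CV AUC; the
    model is then refit on the full training cohort.
    """
    if x.shape[1] == 0:
        raise ValueError("empty feature selection; cannot train")
    yarr = np.asarray(y, dtype=int)
    counts = np.bincount(yarr, minlength=2)
    if counts.min() < 2:
        raise ValueError("need both classes in the training cohort")
    folds = min(folds, int(counts.min()))
    pipe = Pipeline(
        [
            ("scale", StandardScaler()),
            ("svm", SVC(kernel="rbf", C=1.0, gamma="scale", probability=True,
                        random_state=seed)),
        ]
    )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    xv = x.to_numpy(dtype=float)
    with warnings.catch_warnings():
        # sklearn 1.9 deprecation chatter about SVC(probability=True); the
        # Platt-calibrated decision function is exactly what we want here.
        warnings.filterwarnings("ignore", category=FutureWarning)
        cv_scores = cross_val_predict(pipe, xv, yarr, cv=skf, method="predict_proba")[:, 1]
        pipe.fit(xv, yarr)
    cv_auc = roc_auc(cv_scores, yarr).auc
    return TrainedModel(pipe, list(x.columns), cv_scores, float(cv_auc), seed)


# ------------------------------------------------------- orchestration

@dataclass
class NineModelConfig:
    """End-to-end settings for the nine-strategy pipeline."""

    shells: ShellSpec = field(default_factory=ShellSpec)
    hc_config: HCConfig = field(default_factory=HCConfig)
    angle_step: float = 10.0
    slice_size: tuple[int, int] = (224, 224)
    hu_window: tuple[float, float] = DEFAULT_HU_WINDOW
    backbone_seed: int = 0
    backbone_channels: tuple[int, ...] = (16, 32, 64, 128, 256)
    split_ratio: float = 0.2
    folds: int = 10
    seed: int = 0
    fill: float = -1024.0


@dataclass
class ModelReport:
    """Trained-model evaluation bundle for one strategy."""

    strategy: str
    selection: SelectionResult
    cv_auc: float
    test_roc: ROCReport
    cutoff: float
    confusion: ConfusionMatrix
    metrics: MetricsReport
    test_scores: np.ndarray

    def to_dict(self) -> dict:
        return {
            "strategy": self.strategy,
            "n_selected": len(self.selection.selected_names),
            "selected_names": self.selection.selected_names,
            "lambda_min": self.selection.lambda_min,
            "cv_auc": self.cv_auc,
            "test_auc": self.test_roc.auc,
            "test_auc_ci95": list(self.test_roc.ci95),
            "cutoff": self.cutoff,
            "confusion": {
                "tp": self.confusion.tp, "fn": self.confusion.fn,
                "tn": self.confusion.tn, "fp": self.confusion.fp,
            },
            "metrics": self.metrics.rounded(),
        }


@dataclass
class NineModelResult:
    reports: dict[str, ModelReport]
    delong_p: pd.DataFrame
    dca: dict[str, DCACurve]
    split: SplitPlan


def compute_cohort_features(
    cohort, config: NineModelConfig, need_deep: bool, need_sphere: bool
) -> dict[str, pd.DataFrame]:
    """Per-partition feature tables for every subject of a cohort.

    Returns a mapping from table key (``hc_<tag>``, ``hc_sphere``,
    ``dl_<tag>``, ``dl_sphere``) to a subjects × features DataFrame.
    """
    shells = config.shells
    backbone = (
        ConvBackbone(config.backbone_seed, config.backbone_channels)
        if need_deep
        else None
    )
    rows: dict[str, dict[str, pd.Series]] = {}

    def put(key: str, pid: str, series: pd.Series) -> None:
        rows.setdefault(key, {})[pid] = series

    for subject in cohort.subjects:
        v = subject.volume
        if not v.is_isotropic():
            v = resample_isotropic(v)
        centroid = subject.centroid
        masks = {
            tag: make_shell_mask(v, centroid, lo, hi)
            for (lo, hi), tag in zip(shells.intervals, shells.tags)
        }
        if need_sphere:
            masks["sphere"] = make_sphere_mask(v, centroid, shells.r_max)
        for key, mask in masks.items():
            hc = extract_handcrafted(v, mask, config.hc_config)
            put(f"hc_{key}", subject.patient_id, hc.with_partition_suffix())
            if need_deep:
                stack = rotational_slices(
                    v, mask, config.angle_step, config.slice_size, config.fill
                )
                channeled = replicate_channels(stack, window=config.hu_window)
                dl = extract_deep(channeled, backbone, hc.partition_tag)
                put(f"dl_{key}", subject.patient_id, dl.with_partition_suffix())
    return {
        key: pd.DataFrame.from_dict(series_map, orient="index")
        for key, series_map in rows.items()
    }


def assemble_strategy_matrices(
    tables: dict[str, pd.DataFrame], shells: ShellSpec, strategies
) -> dict[str, FeatureMatrix]:
    """Build the per-strategy feature matrices from partition tables."""
    out: dict[str, FeatureMatrix] = {}
    shell_fms = [
        FeatureMatrix(tables[f"hc_{tag}"], tag) for tag in shells.tags
        if f"hc_{tag}" in tables
    ]
    for fm in shell_fms:
        if fm.strategy_tag in strategies:
            out[fm.strategy_tag] = fm
    if "feature_fusion" in strategies:
        out["feature_fusion"] = fuse_features(shell_fms)
    if "image_fusion" in strategies:
        out["image_fusion"] = FeatureMatrix(tables["hc_sphere"], "image_fusion")
    if "feature_fusion_integration" in strategies:
        dl_fms = [FeatureMatrix(tables[f"dl_{tag}"], tag) for tag in shells.tags]
        dl_all = fuse_features(dl_fms, "dl_fusion")
        out["feature_fusion_integration"] = integrate(
            fuse_features(shell_fms), dl_all, "feature_fusion_integration"
        )
    if "image_fusion_integration" in strategies:
        out["image_fusion_integration"] = integrate(
            FeatureMatrix(tables["hc_sphere"], "hc_sphere"),
            FeatureMatrix(tables["dl_sphere"], "dl_sphere"),
            "image_fusion_integration",
        )
    return out


def _fallback_selection(x: pd.DataFrame, y: np.ndarray, sel: SelectionResult) -> SelectionResult:
    """If LASSO selects nothing, keep the best-correlated single feature."""
    xv = x.to_numpy(dtype=float)
    sd = xv.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.abs(
            ((xv - xv.mean(0)) * (y - y.mean())[:, None]).mean(0)
            / (sd * y.std() + 1e-30)
        )
    corr[sd == 0] = -1
    best = str(x.columns[int(np.nanargmax(corr))])
    logger.warning("LASSO selected no features; falling back to %r", best)
    sel.selected_names = [best]
    return sel


def run_nine_models(
    cohort,
    config: NineModelConfig | None = None,
    strategies: tuple[str, ...] | None = None,
) -> NineModelResult:
    """Run the full pipeline for the requested strategies (default: all nine).

    partition → features → fusion → LASSO → SVM → evaluation, sharing one
    stratified 8:2 split across strategies.  Emits the pairwise DeLong
    p-value matrix on test scores and DCA curves for the fusion and
    integration models present.
    """
    config = config or NineModelConfig()
    strategies = tuple(strategies or STRATEGIES)
    unknown = set(strategies) - set(STRATEGIES)
    if unknown:
        raise ValueError(f"unknown strategies: {sorted(unknown)}")

    need_deep = any(s.endswith("_integration") for s in strategies)
    need_sphere = any(s.startswith("image_fusion") for s in strategies)
    tables = compute_cohort_features(cohort, config, need_deep, need_sphere)
    matrices = assemble_strategy_matrices(tables, config.shells, strategies)

    labels = pd.Series(
        {s.patient_id: s.label for s in cohort.subjects}, name="label"
    ).loc[next(iter(matrices.values())).data.index]
    split = make_split(labels, config.split_ratio, config.seed)
    y_train = labels.loc[split.train_ids].to_numpy(dtype=int)
    y_test = labels.loc[split.test_ids].to_numpy(dtype=int)

    reports: dict[str, ModelReport] = {}
    for tag in strategies:
        fm = matrices[tag]
        x_train = fm.data.loc[split.train_ids]
        x_test = fm.data.loc[split.test_ids]
        sel = lasso_select(
            FeatureMatrix(x_train, tag), y_train, config.folds, config.seed
        )
        if not sel.selected_names:
            sel = _fallback_selection(x_train, y_train.astype(float), sel)
        tm = train_svm(x_train[sel.selected_names], y_train, config.folds, config.seed)
        cutoff = select_cutoff(roc_auc(tm.cv_scores, y_train))
        test_scores = tm.predict_scores(x_test[sel.selected_names])
        roc = roc_auc(test_scores, y_test)
        cm = confusion_from_scores(test_scores, y_test, cutoff)
        reports[tag] = ModelReport(
            strategy=tag,
            selection=sel,
            cv_auc=tm.cv_auc,
            test_roc=roc,
            cutoff=cutoff,
            confusion=cm,
            metrics=metrics_from_confusion(cm, cutoff),
            test_scores=test_scores,
        )
        logger.info(
            "%s: %d selected, CV AUC %.3f, test AUC %.3f",
            tag, len(sel.selected_names), tm.cv_auc, roc.auc,
        )

    tags = list(reports)
    pmat = pd.DataFrame(np.ones((len(tags), len(tags))), index=tags, columns=tags)
    for i, a in enumerate(tags):
        for b in tags[i + 1 :]:
            p = delong_test(reports[a].test_scores, reports[b].test_scores, y_test).p
            pmat.loc[a, b] = pmat.loc[b, a] = p

    dca = {
        tag: dca_curve(reports[tag].test_scores, y_test)
        for tag in FUSION_STRATEGIES
        if tag in reports
    }
    return NineModelResult(reports, pmat, dca, split)
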