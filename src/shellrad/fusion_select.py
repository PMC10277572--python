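"""Assembly of the nine model feature sets and LASSO feature selection.

Nine strategies combine the per-partition feature vectors:

* the five single-shell handcrafted sets (``shell_0_3`` … ``shell_12_15``);
* ``feature_fusion`` — column-wise concatenation of the five shell sets
  (5 × 1688 = 8440 handcrafted features);
* ``image_fusion`` — one handcrafted set extracted from the fused 0–15 mm
  sphere (1688 features);
* ``feature_fusion_integration`` — feature fusion plus the five per-shell
  deep vectors (8440 + 5 × 256 = 9720);
* ``image_fusion_integration`` — the sphere's handcrafted plus deep
  vectors (1688 + 256 = 1944).

Selection is an L1-penalized linear regression of the 0/1 label on
standardized features; the penalty is chosen where the 10-fold
cross-validated mean squared error is lowest, and the features with
nonzero coefficients at that penalty form the selected set.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso, lasso_path
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)

__all__ = [
    "STRATEGIES",
    "FeatureMatrix",
    "SelectionResult",
    "fuse_features",
    "integrate",
    "lasso_select",
]

STRATEGIES = (
    "shell_0_3",
    "shell_3_6",
    "shell_6_9",
    "shell_9_12",
    "shell_12_15",
    "feature_fusion",
    "image_fusion",
    "feature_fusion_integration",
    "image_fusion_integration",
)


@dataclass
class FeatureMatrix:
    """Subjects × named features for one model strategy."""

    data: pd.DataFrame  # index = patient ids, columns = feature names
    strategy_tag: str

    def __post_init__(self) -> None:
        if self.data.columns.has_duplicates:
            raise ValueError("feature matrix has duplicate column names")
        if self.data.isna().any().any():
            raise ValueError("feature matrix contains missing values")

    @property
    def subjects(self) -> list[str]:
        return list(self.data.index)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


def _check_same_subjects(frames: list[pd.DataFrame]) -> None:
    ref = frames[0].index
    for df in frames[1:]:
        if len(df.index) != len(ref) or not df.index.equals(ref):
            raise ValueError(
                "feature matrices cover different subjects or subject order"
            )


def fuse_features(per_shell: list[FeatureMatrix], strategy_tag: str = "feature_fusion") -> FeatureMatrix:
    """Column-wise concatenation of per-shell matrices (feature fusion)."""
    frames = [fm.data for fm in per_shell]
    _check_same_subjects(frames)
    merged = pd.concat(frames, axis=1)
    if merged.columns.has_duplicates:
        raise ValueError("fused matrices must have globally unique column names")
    return FeatureMatrix(merged, strategy_tag)


def integrate(hc: FeatureMatrix, dl: FeatureMatrix, strategy_tag: str) -> FeatureMatrix:
    """Concatenate handcrafted and deep feature sets (integration)."""
    _check_same_subjects([hc.data, dl.data])
    collisions = hc.data.columns.intersection(dl.data.columns)
    if len(collisions):
        raise ValueError(f"column-name collision on integration: {list(collisions[:5])}")
    return FeatureMatrix(pd.concat([hc.data, dl.data], axis=1), strategy_tag)


@dataclass
class SelectionResult:
    """Outcome of the CV-MSE-minimizing LASSO selection."""

    selected_names: list[str]
    lambda_min: float
    cv_lambdas: np.ndarray
    cv_mse_mean: np.ndarray
    cv_mse_sd: np.ndarray
    seed: int
    dropped_constant: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        payload = {
            "selected_names": self.selected_names,
            "lambda_min": self.lambda_min,
            "seed": self.seed,
            "dropped_constant": self.dropped_constant,
            "cv_curve": {
                "lambda": self.cv_lambdas.tolist(),
                "mse_mean": self.cv_mse_mean.tolist(),
                "mse_sd": self.cv_mse_sd.tolist(),
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _lambda_grid(xs: np.ndarray, y: np.ndarray, n_lambdas: int, eps: float) -> np.ndarray:
    n = xs.shape[0]
    yc = y - y.mean()
    lam_max = np.max(np.abs(xs.T @ yc)) / n
    lam_max = max(lam_max, 1e-12)
    return np.logspace(np.log10(lam_max), np.log10(lam_max * eps), n_lambdas)


def lasso_select(
    x: FeatureMatrix,
    y,
    folds: int = 10,
    seed: int = 0,
    n_lambdas: int = 100,
    lambda_eps: float = 1e-4,
) -> SelectionResult:
    """Select features with nonzero LASSO coefficients at the CV-MSE minimum.

    The 0/1 label is regressed on internally standardized features over a
    descending log-spaced penalty grid (100 values from the smallest
    penalty that zeroes every coefficient down to 1e-4 of it).  Mean
    squared error is estimated by stratified, seeded 10-fold CV; ties in
    the CV curve break toward the larger penalty (the sparser model).
    """
    y = np.asarray(y, dtype=float).ravel()
    df = x.data
    if len(y) != len(df):
        raise ValueError("label vector does not match the feature matrix rows")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("labels are degenerate (a single class)")
    if counts.min() < 2:
        raise ValueError("need at least 2 subjects per class")

    values = df.to_numpy(dtype=float)
    sd = values.std(axis=0)
    keep = sd > 0
    dropped = [c for c, k in zip(df.columns, keep) if not k]
    if dropped:
        logger.warning("dropping %d constant feature column(s)", len(dropped))
    names = np.asarray(df.columns)[keep]
    xs = (values[:, keep] - values[:, keep].mean(axis=0)) / sd[keep]

    lambdas = _lambda_grid(xs, y, n_lambdas, lambda_eps)
    folds = min(folds, int(counts.min()))
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    mse = np.zeros((folds, len(lambdas)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for k, (tr, va) in enumerate(skf.split(xs, y)):
            # lasso_path fits without an intercept; center the fold's labels.
            _, coefs, _ = lasso_path(xs[tr], y[tr] - y[tr].mean(), alphas=lambdas)
            preds = xs[va] @ coefs + y[tr].mean()
            mse[k] = np.mean((preds - y[va][:, None]) ** 2, axis=0)
        mean_mse = mse.mean(axis=0)
        sd_mse = mse.std(axis=0, ddof=1)
        # Grid is descending, so the first minimum is the largest such lambda.
        best = int(np.argmin(mean_mse))
        lam = float(lambdas[best])

        model = Lasso(alpha=lam, max_iter=50000)
        model.fit(xs, y)
    selected = [str(n) for n, c in zip(names, model.coef_) if c != 0.0]
    return SelectionResult(
        selected_names=selected,
        lambda_min=lam,
        cv_lambdas=lambdas,
        cv_mse_mean=mean_mse,
        cv_mse_sd=sd_mse,
        seed=seed,
        dropped_constant=dropped,
    )
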