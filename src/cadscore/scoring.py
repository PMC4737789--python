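"""Linear-discriminant combination of the acoustic features into the
0-100 CAD-score.

A Fisher linear discriminant (pooled within-class covariance) is fitted
twice: on the full feature set (FPR, PCASpec, AMI, S4Amp) and on the
reduced set (AMI, S4Amp) used for subjects with short diastasis.  Each
branch's raw discriminant is standardised on the training sample, so one
shared affine calibration (slope = target SD, offset = target mean,
defaults 12 and 25) maps both branches onto the population score scale.
Scores are clipped to [0, 100] and categorised as low (<= 20),
intermediate (20, 30] or high (> 30).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .config import DEFAULT_CONFIG, AlgorithmConfig
from .diagnostics import roc_auc
from .errors import FeatureMissingError, InsufficientDataError, ParameterError
from .spectral_features import FeatureVector

FULL_FEATURES = ("fpr", "pcaspec", "ami", "s4amp")
REDUCED_FEATURES = ("ami", "s4amp")


@dataclass
class DiscriminantModel:
    weights_full: np.ndarray
    intercept_full: float
    weights_reduced: np.ndarray
    intercept_reduced: float
    calibration_slope: float
    calibration_offset: float
    metadata: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "feature_order_full": list(FULL_FEATURES),
                "feature_order_reduced": list(REDUCED_FEATURES),
                "weights_full": self.weights_full.tolist(),
                "intercept_full": self.intercept_full,
                "weights_reduced": self.weights_reduced.tolist(),
                "intercept_reduced": self.intercept_reduced,
                "calibration_slope": self.calibration_slope,
                "calibration_offset": self.calibration_offset,
                "metadata": self.metadata,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "DiscriminantModel":
        d = json.loads(text)
        return cls(
            weights_full=np.asarray(d["weights_full"], dtype=float),
            intercept_full=float(d["intercept_full"]),
            weights_reduced=np.asarray(d["weights_reduced"], dtype=float),
            intercept_reduced=float(d["intercept_reduced"]),
            calibration_slope=float(d["calibration_slope"]),
            calibration_offset=float(d["calibration_offset"]),
            metadata=d.get("metadata", {}),
        )


@dataclass
class CADScore:
    value: float                 # points, clipped to [0, 100]
    category: str                # low | intermediate | high
    short_diastasis_used: bool


def score_category(value: float, config: AlgorithmConfig = DEFAULT_CONFIG) -> str:
    if value <= config.score_low_max:
        return "low"
    if value <= config.score_intermediate_max:
        return "intermediate"
    return "high"


def _fisher_direction(X: np.ndarray, y: np.ndarray, ridge: float) -> tuple[np.ndarray, float]:
    """Fisher LDA direction from the pooled within-class covariance.

    Returns (w, b) so that the raw discriminant is w.x + b, oriented with
    larger values for the positive class.  A small ridge keeps the pooled
    covariance invertible for (near-)degenerate inputs.
    """
    X0, X1 = X[y == 0], X[y == 1]
    mu0, mu1 = X0.mean(axis=0), X1.mean(axis=0)
    n0, n1 = len(X0), len(X1)
    S0 = np.cov(X0, rowvar=False, bias=False) * (n0 - 1)
    S1 = np.cov(X1, rowvar=False, bias=False) * (n1 - 1)
    Sw = (np.atleast_2d(S0) + np.atleast_2d(S1)) / (n0 + n1 - 2)
    scale = float(np.trace(Sw)) / Sw.shape[0] or 1.0
    Sw = Sw + ridge * scale * np.eye(Sw.shape[0])
    w = np.linalg.solve(Sw, mu1 - mu0)
    b = -float(w @ (mu0 + mu1) / 2.0)
    return w, b


def train_discriminant(
    features: Sequence[FeatureVector],
    labels: Sequence[int],
    config: AlgorithmConfig = DEFAULT_CONFIG,
) -> DiscriminantModel:
    """Fit the full and reduced discriminants and the score calibration.

    The full branch is trained on subjects with all four features; the
    reduced (AMI, S4Amp) branch on every subject.  Both raw discriminants
    are standardised on their training sample (mean 0, SD 1, folded into
    the weights) so the shared affine calibration produces training scores
    with mean ``score_mean`` and SD ``score_sd`` before clipping.
    """
    y = np.asarray(labels, dtype=int)
    if y.shape[0] != len(features):
        raise ParameterError("features and labels length mismatch")

    full_rows = [
        (fv.as_full_array(), lab)
        for fv, lab in zip(features, y)
        if not fv.short_diastasis and fv.fpr is not None and fv.pcaspec is not None
    ]
    Xf = np.array([r for r, _ in full_rows], dtype=float)
    yf = np.array([l for _, l in full_rows], dtype=int)
    Xr = np.array([fv.as_reduced_array() for fv in features], dtype=float)

    for name, yy, min_n in (("full", yf, 20), ("reduced", y, 10)):
        if yy.size == 0 or min((yy == 0).sum(), (yy == 1).sum()) < min_n:
            raise InsufficientDataError(
                f"need >= {min_n} subjects per class for the {name} discriminant"
            )

    wf, bf = _fisher_direction(Xf, yf, config.lda_ridge)
    wr, br = _fisher_direction(Xr, y, config.lda_ridge)

    raw_f = Xf @ wf + bf
    raw_r = Xr @ wr + br

    def _standardise(w, b, raw):
        sd = float(np.std(raw))
        if sd <= 0:
            sd = 1.0
        return w / sd, (b - float(np.mean(raw))) / sd

    wf, bf = _standardise(wf, bf, raw_f)
    wr, br = _standardise(wr, br, raw_r)

    return DiscriminantModel(
        weights_full=wf,
        intercept_full=bf,
        weights_reduced=wr,
        intercept_reduced=br,
        calibration_slope=config.score_sd,
        calibration_offset=config.score_mean,
        metadata={
            "n_training": int(y.size),
            "n_full": int(yf.size),
            "prevalence": float(y.mean()),
        },
    )


def cad_score(
    fv: FeatureVector,
    model: DiscriminantModel,
    config: AlgorithmConfig = DEFAULT_CONFIG,
) -> CADScore:
    """Score one subject: raw discriminant -> affine calibration -> clip."""
    if fv.short_diastasis:
        x = fv.as_reduced_array()
        if np.any(~np.isfinite(x)):
            raise FeatureMissingError("AMI/S4Amp required for the reduced score")
        raw = float(x @ model.weights_reduced + model.intercept_reduced)
        used_reduced = True
    else:
        x = fv.as_full_array()
        if np.any(~np.isfinite(x)):
            raise FeatureMissingError(
                "full score requires fpr, pcaspec, ami and s4amp"
            )
        raw = float(x @ model.weights_full + model.intercept_full)
        used_reduced = False
    value = float(np.clip(model.calibration_slope * raw + model.calibration_offset, 0.0, 100.0))
    return CADScore(value=value, category=score_category(value, config),
                    short_diastasis_used=used_reduced)


def score_cohort(
    features: Sequence[FeatureVector],
    model: DiscriminantModel,
    config: AlgorithmConfig = DEFAULT_CONFIG,
) -> np.ndarray:
    return np.array([cad_score(fv, model, config).value for fv in features])


@dataclass
class CVResult:
    mean_auc: float
    per_repeat_auc: np.ndarray

    @property
    def sd_auc(self) -> float:
        return float(np.std(self.per_repeat_auc, ddof=1))


def cross_validate(
    features: Sequence[FeatureVector],
    labels: Sequence[int],
    repeats: int = 20,
    folds: int = 10,
    seed: int = 0,
    config: AlgorithmConfig = DEFAULT_CONFIG,
) -> CVResult:
    """Repeated stratified k-fold cross-validation of the discriminant.

    For each repeat the fold assignment is re-randomised; held-out scores
    are pooled across folds and summarised by one AUC per repeat.
    """
    y = np.asarray(labels, dtype=int)
    if y.size < folds:
        raise InsufficientDataError("fewer subjects than folds")
    features = list(features)
    rng = np.random.default_rng(seed)
    aucs = []
    for _ in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True,
                              random_state=int(rng.integers(2**31 - 1)))
        held_out = np.empty(y.size)
        for train_idx, test_idx in skf.split(np.zeros(y.size), y):
            m = train_discriminant([features[i] for i in train_idx], y[train_idx], config)
            held_out[test_idx] = score_cohort([features[i] for i in test_idx], m, config)
        aucs.append(roc_auc(held_out, y).auc)
    return CVResult(mean_auc=float(np.mean(aucs)), per_repeat_auc=np.array(aucs))
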