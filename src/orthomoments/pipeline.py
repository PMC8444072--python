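"""End-to-end study orchestration and performance metrics.

Two study designs are wired together here:

* the *wing study* — multi-class classification of binary wing images
  from pose-normalized Krawtchouk moment features (Z-score, Q-mode PCA,
  Fisher LDA, Gaussian kernel discriminant), reported as a training-set
  confusion matrix with a beta-posterior accuracy summary, alongside a
  landmark-coordinate comparison arm on the same samples;
* the *mass study* — two-class classification of grayscale mass images
  from Krawtchouk + generalized pseudo-Zernike feature blocks (per-block
  top-|t| selection, PCA, LDA, kernel discriminant) over repeated
  stratified 70/30 splits, followed by feature-fusion models I-IV that
  combine categorical expert features with the predicted probability of
  malignancy P(mal).

All fitted state (scalers, selections, loadings, discriminants,
bandwidths) derives from training rows only; P(mal) for training rows
of the fusion models comes from out-of-fold prediction so the fused
models never see in-sample probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bayes import PosteriorAccuracy, accuracy_from_confusion, posterior_accuracy
from .features import (
    FeatureSpaceModel,
    fit_feature_space,
    lda_fit,
    lda_project,
    pca_project,
    qmode_pca_fit,
    t_select,
    transform_feature_space,
    zscore_apply,
    zscore_fit,
)
from .kde_classifier import kd_fit, kd_predict
from .krawtchouk import km_invariant_features, km_moments, krawtchouk_basis
from .pseudozernike import GPZMParams, gpzm_features
from .synthetic import MassSpec, WingSpec, gen_masses, gen_wings, landmark_features

__all__ = [
    "stratified_split",
    "confusion",
    "metrics_from_confusion",
    "MetricReport",
    "WingStudyConfig",
    "WingStudyReport",
    "run_wing_study",
    "MassStudyConfig",
    "MassStudyReport",
    "run_mass_study",
    "FUSION_MODELS",
]

EXPERT_FEATURES = ["assessment", "shape", "margin", "density", "subtlety"]

#: feature sets of the four fusion models: (use assessment, use P(mal))
FUSION_MODELS = {
    "I": dict(assessment=True, pmal=True),
    "II": dict(assessment=True, pmal=False),
    "III": dict(assessment=False, pmal=True),
    "IV": dict(assessment=False, pmal=False),
}


def stratified_split(
    labels: np.ndarray, train_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class random split preserving class proportions within one sample."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train fraction must lie strictly inside (0, 1)")
    labels = np.asarray(labels)
    train, test = [], []
    for c in np.unique(labels):
        idx = np.where(labels == c)[0]
        idx = rng.permutation(idx)
        n_train = int(round(train_fraction * len(idx)))
        n_train = min(max(n_train, 1), len(idx) - 1)
        train.extend(idx[:n_train])
        test.extend(idx[n_train:])
    return np.sort(np.asarray(train)), np.sort(np.asarray(test))


def confusion(y_true, y_pred, classes=None) -> tuple[np.ndarray, np.ndarray]:
    """Square count matrix (rows = true class, cols = predicted)."""
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    if classes is None:
        classes = np.unique(np.concatenate([y_true, y_pred]))
    classes = np.asarray(classes)
    lookup = {c: i for i, c in enumerate(classes)}
    M = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        M[lookup[t], lookup[p]] += 1
    return M, classes


def metrics_from_confusion(
    M: np.ndarray, classes: np.ndarray | None = None, positive=None
) -> dict[str, float]:
    """Accuracy (trace/total) plus sensitivity/specificity for 2 classes.

    Sensitivity is the probability of predicting the positive class
    given a positive sample; specificity the analogue for the negative
    class.  A conditional metric whose class has no samples is NaN.
    """
    M = np.asarray(M)
    if np.any(M < 0):
        raise ValueError("confusion counts must be non-negative")
    total = M.sum()
    out = {"accuracy": float(np.trace(M) / total) if total else float("nan")}
    if positive is not None:
        if M.shape != (2, 2) or classes is None or len(classes) != 2:
            raise ValueError("sensitivity/specificity require a 2x2 matrix with classes")
        pos = int(np.where(np.asarray(classes) == positive)[0][0])
        neg = 1 - pos
        tp, fn = M[pos, pos], M[pos, neg]
        tn, fp = M[neg, neg], M[neg, pos]
        out["sensitivity"] = float(tp / (tp + fn)) if (tp + fn) else float("nan")
        out["specificity"] = float(tn / (tn + fp)) if (tn + fp) else float("nan")
    return out


@dataclass
class MetricReport:
    """Per-repeat metrics with mean and standard error (sd / sqrt(R))."""

    accuracy: np.ndarray
    sensitivity: np.ndarray | None = None
    specificity: np.ndarray | None = None

    def _stats(self, values: np.ndarray) -> tuple[float, float]:
        values = np.asarray(values, dtype=float)
        se = values.std(ddof=1) / np.sqrt(len(values)) if len(values) > 1 else 0.0
        return float(values.mean()), float(se)

    def summary(self) -> dict[str, tuple[float, float]]:
        out = {"accuracy": self._stats(self.accuracy)}
        if self.sensitivity is not None:
            out["sensitivity"] = self._stats(self.sensitivity)
        if self.specificity is not None:
            out["specificity"] = self._stats(self.specificity)
        return out

    def format_percent(self) -> dict[str, str]:
        """``'70 ± 1'``-style strings (percent, mean ± standard error)."""
        return {
            k: f"{100 * m:.0f} ± {100 * se:.0f}" for k, (m, se) in self.summary().items()
        }


# ---------------------------------------------------------------------------
# wing study
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WingStudyConfig:
    wing_spec: WingSpec = field(default_factory=WingSpec)
    km_order: int = 200
    p: float = 0.5
    mass_fraction: float = 0.25
    n_components: int | None = 60
    beta: float | None = None
    landmark_components: int = 15
    #: evaluate the moment arm on an independent batch drawn from the
    #: same class geometry (same seed, shifted sample substreams)
    heldout: bool = False


@dataclass
class WingStudyReport:
    classes: np.ndarray
    train_confusion: np.ndarray
    train_posterior: PosteriorAccuracy
    landmark_confusion: np.ndarray
    landmark_posterior: PosteriorAccuracy
    baseline_posterior: PosteriorAccuracy
    test_confusion: np.ndarray | None = None
    test_posterior: PosteriorAccuracy | None = None


def _wing_features(images: np.ndarray, cfg: WingStudyConfig) -> np.ndarray:
    frame = images[0].shape
    return np.stack(
        [
            km_invariant_features(
                img, cfg.km_order, p=cfg.p, mass_fraction=cfg.mass_fraction, frame=frame
            )
            for img in images
        ]
    )


def _fit_predict_arm(X, labels, n_components):
    n = len(labels)
    k = min(n_components, n - 1) if n_components is not None else None
    model = fit_feature_space(X, labels, select_fraction=None, beta=None, n_components=k)
    D = transform_feature_space(X, model)
    kde = kd_fit(D, labels, bandwidth="scott", priors="empirical")
    pred, _ = kd_predict(kde, D)
    return model, kde, pred


def run_wing_study(cfg: WingStudyConfig) -> WingStudyReport:
    """Train the moment and landmark arms, report training confusions.

    With the small per-class sample sizes of this design the classifier
    is evaluated on its training set (the posterior accuracy summary
    quantifies the uncertainty); ``heldout_seed`` additionally
    generates an independent batch from the same spec and reports
    held-out performance of the moment arm.
    """
    images, labels, landmarks = gen_wings(cfg.wing_spec)
    X = _wing_features(images, cfg)
    model, kde, pred = _fit_predict_arm(X, labels, cfg.n_components)
    M, classes = confusion(labels, pred, np.unique(labels))
    post = posterior_accuracy(*accuracy_from_confusion(M))

    F = landmark_features(landmarks)
    _, _, lm_pred = _fit_predict_arm(F, labels, cfg.landmark_components)
    Ml, _ = confusion(labels, lm_pred, classes)
    lm_post = posterior_accuracy(*accuracy_from_confusion(Ml))

    majority = int(np.max(np.bincount(labels)))
    baseline = posterior_accuracy(majority, len(labels))

    report = WingStudyReport(
        classes=classes,
        train_confusion=M,
        train_posterior=post,
        landmark_confusion=Ml,
        landmark_posterior=lm_post,
        baseline_posterior=baseline,
    )
    if cfg.heldout:
        from dataclasses import replace

        test_spec = replace(cfg.wing_spec, sample_offset=cfg.wing_spec.sample_offset + 100_000)
        t_images, t_labels, _ = gen_wings(test_spec)
        Xt = _wing_features(t_images, cfg)
        Dt = transform_feature_space(Xt, model)
        t_pred, _ = kd_predict(kde, Dt)
        Mt, _ = confusion(t_labels, t_pred, classes)
        report.test_confusion = Mt
        report.test_posterior = posterior_accuracy(*accuracy_from_confusion(Mt))
    return report


# ---------------------------------------------------------------------------
# mass study
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TwoBlockModel:
    """Per-block scaler + |t| selection, then shared PCA/LDA."""

    scalers: tuple
    selections: tuple
    pca: object
    lda: object


def fit_two_block_pipeline(
    blocks: list[np.ndarray], labels: np.ndarray, t_fraction: float, beta: float
) -> TwoBlockModel:
    scalers, selections, parts = [], [], []
    for B in blocks:
        scaler = zscore_fit(B)
        Z = zscore_apply(B, scaler)
        sel = t_select(Z, labels, t_fraction)
        scalers.append(scaler)
        selections.append(sel)
        parts.append(Z[:, sel])
    Z = np.hstack(parts)
    pca = qmode_pca_fit(Z, beta=beta)
    s = np.unique(labels).size
    k = max(pca.k, s - 1)
    if k != pca.k:
        pca = type(pca)(
            mean=pca.mean,
            components=pca.components,
            explained_variance_ratio=pca.explained_variance_ratio,
            scores=pca.scores,
            k=min(k, pca.components.shape[0]),
            beta=pca.beta,
        )
    lda = lda_fit(pca.scores[:, : pca.k], labels)
    return TwoBlockModel(tuple(scalers), tuple(selections), pca, lda)


def transform_two_block(blocks: list[np.ndarray], model: TwoBlockModel) -> np.ndarray:
    parts = [
        zscore_apply(B, sc)[:, sel]
        for B, sc, sel in zip(blocks, model.scalers, model.selections)
    ]
    return lda_project(pca_project(np.hstack(parts), model.pca), model.lda)


@dataclass(frozen=True)
class MassStudyConfig:
    mass_spec: MassSpec = field(default_factory=MassSpec)
    km_order: int = 24
    gpzm_order: int = 12
    p: float = 0.5
    alpha: float = 0.0
    t_fraction: float = 0.01
    beta: float = 0.95
    train_fraction: float = 0.7
    n_repeats: int = 10
    oof_folds: int = 5
    seed: int = 0
    positive_label: str = "malignant"


@dataclass
class MassStudyReport:
    image_arm: MetricReport
    fusion: dict[str, MetricReport]
    classes: np.ndarray
    n_repeats: int


def mass_image_features(
    images: np.ndarray, cfg: MassStudyConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Label-free KM and GPZM feature blocks for every mass image."""
    S = images[0].shape[0]
    basis = krawtchouk_basis(cfg.km_order, S, cfg.p)
    km = np.stack([km_moments(img, basis, basis).Q.ravel() for img in images])
    params = GPZMParams(n_max=cfg.gpzm_order, alpha=cfg.alpha)
    gp = np.stack([gpzm_features(img, params) for img in images])
    return km, gp


def _oof_pmal(
    blocks: list[np.ndarray],
    labels: np.ndarray,
    cfg: MassStudyConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Out-of-fold P(mal) for training rows (no in-sample leakage)."""
    n = len(labels)
    folds = np.zeros(n, dtype=int)
    for c in np.unique(labels):
        idx = rng.permutation(np.where(labels == c)[0])
        folds[idx] = np.arange(len(idx)) % cfg.oof_folds
    pmal = np.zeros(n)
    for f in range(cfg.oof_folds):
        tr, te = folds != f, folds == f
        if te.sum() == 0:
            continue
        model = fit_two_block_pipeline([B[tr] for B in blocks], labels[tr], cfg.t_fraction, cfg.beta)
        D_tr = transform_two_block([B[tr] for B in blocks], model)
        kde = kd_fit(D_tr, labels[tr], positive_label=cfg.positive_label)
        _, proba = kd_predict(kde, transform_two_block([B[te] for B in blocks], model))
        pos = int(np.where(kde.classes == cfg.positive_label)[0][0])
        pmal[te] = proba[:, pos]
    return pmal


def _one_hot_expert(expert: pd.DataFrame, with_assessment: bool) -> np.ndarray:
    cols = [c for c in EXPERT_FEATURES if with_assessment or c != "assessment"]
    dummies = pd.get_dummies(expert[cols].astype("category"), columns=cols)
    return dummies.to_numpy(dtype=float)


def run_mass_study(cfg: MassStudyConfig) -> MassStudyReport:
    """Repeated 70/30 evaluation of the image arm and fusion models I-IV."""
    images, labels, expert = gen_masses(cfg.mass_spec)
    km, gp = mass_image_features(images, cfg)
    onehot = {
        True: _one_hot_expert(expert, with_assessment=True),
        False: _one_hot_expert(expert, with_assessment=False),
    }
    classes = np.unique(labels)
    rows_image = {"accuracy": [], "sensitivity": [], "specificity": []}
    rows_fusion = {
        name: {"accuracy": [], "sensitivity": [], "specificity": []} for name in FUSION_MODELS
    }
    for rep in range(cfg.n_repeats):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=cfg.seed, spawn_key=(10, rep)))
        tr, te = stratified_split(labels, cfg.train_fraction, rng)
        blocks_tr = [km[tr], gp[tr]]
        blocks_te = [km[te], gp[te]]
        model = fit_two_block_pipeline(blocks_tr, labels[tr], cfg.t_fraction, cfg.beta)
        D_tr = transform_two_block(blocks_tr, model)
        D_te = transform_two_block(blocks_te, model)
        kde = kd_fit(D_tr, labels[tr], positive_label=cfg.positive_label)
        pred_te, proba_te = kd_predict(kde, D_te)
        pos = int(np.where(kde.classes == cfg.positive_label)[0][0])
        M, _ = confusion(labels[te], pred_te, classes)
        met = metrics_from_confusion(M, classes, positive=cfg.positive_label)
        for k, v in met.items():
            rows_image[k].append(v)

        pmal_train = _oof_pmal(blocks_tr, labels[tr], cfg, rng)
        pmal_test = proba_te[:, pos]
        for name, opts in FUSION_MODELS.items():
            X_tr = onehot[opts["assessment"]][tr]
            X_te = onehot[opts["assessment"]][te]
            if opts["pmal"]:
                X_tr = np.column_stack([X_tr, pmal_train])
                X_te = np.column_stack([X_te, pmal_test])
            fkde = kd_fit(X_tr, labels[tr], positive_label=cfg.positive_label)
            fpred, _ = kd_predict(fkde, X_te)
            Mf, _ = confusion(labels[te], fpred, classes)
            fmet = metrics_from_confusion(Mf, classes, positive=cfg.positive_label)
            for k, v in fmet.items():
                rows_fusion[name][k].append(v)

    image_report = MetricReport(
        accuracy=np.asarray(rows_image["accuracy"]),
        sensitivity=np.asarray(rows_image["sensitivity"]),
        specificity=np.asarray(rows_image["specificity"]),
    )
    fusion = {
        name: MetricReport(
            accuracy=np.asarray(r["accuracy"]),
            sensitivity=np.asarray(r["sensitivity"]),
            specificity=np.asarray(r["specificity"]),
        )
        for name, r in rows_fusion.items()
    }
    return MassStudyReport(
        image_arm=image_report, fusion=fusion, classes=classes, n_repeats=cfg.n_repeats
    )
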