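"""PCA-LDA classification, wavenumber weighting and lesion-level evaluation.

The discriminant model decomposes preprocessed spectra into principal
components covering a target explained variance (default 90%) and fits a
two-class Fisher linear discriminant on the component scores, yielding a
single LD score per spectrum.  The composition of PCA loadings and LDA
direction is an affine map of the input spectrum, so the discriminant can
be projected back onto the wavenumber axis as a weighting vector — a
measure of each wavenumber's importance to the classification.  When the
preprocessing includes a derivative step, the weights live on
derivative-spectrum coordinates and are reported as such.

Lesion-level prognosis uses a simple majority vote over the lesion's
spectra (a lesion is called transforming when at least 50% of its spectra
are predicted transforming; the threshold is inclusive and configurable).
Evaluation aggregates leave-one-pair-out folds into spectrum- and
lesion-level sensitivity/specificity, vertically averaged ROC curves and
per-lesion correct-prediction frequencies.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve, auc as sk_auc

from .preprocessing import (
    FeaturePCA,
    PipelineConfig,
    PipelineState,
    build_steps,
)
from .spectra_core import Cohort, HyperspectralImage, SpectralAxis
from .pipeline_search import CVSplit, lopocv_splits, subsample_balanced, _pooled_matrix

__all__ = [
    "LDModel",
    "WeightVector",
    "FoldPrediction",
    "EvaluationReport",
    "fit_pca_lda",
    "backproject_weights",
    "predict_spectra",
    "lesion_vote",
    "aggregate_report",
    "roc_curves",
    "probability_map",
    "run_lopocv_evaluation",
]

CLASSES = ("NT", "T")
FPR_GRID = np.linspace(0.0, 1.0, 101)


@dataclass
class LDModel:
    """A fitted PCA-LDA discriminant.

    LD score of a spectrum x is ``((x - pca_mean) @ loadings.T) @
    lda_direction``; class T is predicted when the score strictly exceeds
    ``lda_threshold`` (a score exactly at threshold is called NT).
    Probabilities come from a logistic calibration of the training LD
    scores.
    """

    pca: FeaturePCA
    lda_direction: np.ndarray
    lda_threshold: float
    calibration: tuple[float, float]  # (slope, intercept) on the LD score
    axis: SpectralAxis  # reduced (post-excision) axis the model was fit on
    classes: tuple[str, str] = CLASSES

    @property
    def n_features_in_(self) -> int:
        return self.pca.loadings_.shape[1]

    def ld_scores(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"feature dimension mismatch: expected {self.n_features_in_}, "
                f"got {X.shape[1]}"
            )
        return self.pca.transform(X) @ self.lda_direction


@dataclass
class WeightVector:
    """Per-wavenumber discriminant weighting on the reduced axis."""

    axis: SpectralAxis
    weights: np.ndarray
    top_features: list[tuple[float, float]]  # (wavenumber, |weight|), ranked

    def __post_init__(self) -> None:
        if self.weights.size != len(self.axis):
            raise ValueError("weights length must match the reduced axis")


@dataclass
class FoldPrediction:
    """Predictions of one LOPOCV fold: per test lesion, per spectrum."""

    split: CVSplit
    lesions: dict[str, dict]  # lesion_id -> {scores, classes, probs, truth}
    weighting: WeightVector


@dataclass
class EvaluationReport:
    """Aggregated LOPOCV evaluation of one pipeline."""

    sensitivity_spectrum: tuple[float, float]  # mean, SD (%)
    specificity_spectrum: tuple[float, float]
    sensitivity_lesion: tuple[float, float]
    specificity_lesion: tuple[float, float]
    per_lesion_frequency: dict[str, float]
    per_lesion_appearances: dict[str, int]
    mislabelled: list[str]
    roc: dict
    weighting_mean: WeightVector
    weighting_folds: list[WeightVector] = field(repr=False, default_factory=list)
    folds: list[FoldPrediction] = field(repr=False, default_factory=list)

    def to_json(self, path: str | Path) -> None:
        d = {
            "sensitivity_spectrum_pct": list(self.sensitivity_spectrum),
            "specificity_spectrum_pct": list(self.specificity_spectrum),
            "sensitivity_lesion_pct": list(self.sensitivity_lesion),
            "specificity_lesion_pct": list(self.specificity_lesion),
            "per_lesion_frequency": self.per_lesion_frequency,
            "per_lesion_appearances": self.per_lesion_appearances,
            "mislabelled": self.mislabelled,
            "roc_auc_mean": self.roc["auc_mean"],
            "weighting_top_features": self.weighting_mean.top_features,
        }
        Path(path).write_text(json.dumps(d, indent=1))


# ---------------------------------------------------------------------------
# Model fitting
# ---------------------------------------------------------------------------


def fit_pca_lda(
    X: np.ndarray,
    y: np.ndarray,
    axis: SpectralAxis,
    explained_variance: float = 90.0,
    ridge: float = 1e-8,
) -> LDModel:
    """Fit PCA (to the explained-variance target) then a two-class Fisher
    discriminant on the component scores.

    ``y`` codes NT as 0 and T as 1.  The discriminant direction is
    ``Sw^-1 (mu_T - mu_NT)`` with pooled within-class covariance Sw (plus
    a small ridge for numerical stability); the threshold sits midway
    between the projected class means, and orientation guarantees the T
    class scores higher.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y).astype(int)
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("training data must contain both classes (0=NT, 1=T)")
    pca = FeaturePCA(explained_variance).fit(X)
    S = pca.transform(X)
    S1, S0 = S[y == 1], S[y == 0]
    mu1, mu0 = S1.mean(axis=0), S0.mean(axis=0)
    n1, n0 = S1.shape[0], S0.shape[0]
    k = S.shape[1]
    if n1 < 2 or n0 < 2:
        Sw = np.eye(k)
    else:
        Sw = ((n1 - 1) * np.cov(S1, rowvar=False) + (n0 - 1) * np.cov(S0, rowvar=False)) / (
            n1 + n0 - 2
        )
        Sw = np.atleast_2d(Sw)
    w = np.linalg.solve(Sw + ridge * np.trace(Sw) / k * np.eye(k), mu1 - mu0)
    threshold = float(w @ (mu1 + mu0) / 2.0)

    scores = S @ w
    slope, intercept = _calibrate_logistic(scores - threshold, y)
    return LDModel(pca, w, threshold, (slope, intercept), axis)


def _calibrate_logistic(centred_scores: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    lr = LogisticRegression(C=1.0, max_iter=1000)
    lr.fit(centred_scores[:, None], y)
    return float(lr.coef_[0, 0]), float(lr.intercept_[0])


def predict_spectra(model: LDModel, X: np.ndarray):
    """Per-spectrum LD score, predicted class and probability of T.

    Class is T iff the LD score strictly exceeds the threshold (a tie is
    called NT); probability is the logistic of the calibrated score.
    """
    scores = model.ld_scores(X)
    classes = np.where(scores > model.lda_threshold, "T", "NT")
    a, b = model.calibration
    probs = 1.0 / (1.0 + np.exp(-(a * (scores - model.lda_threshold) + b)))
    return scores, classes, probs


def backproject_weights(
    model: LDModel, n_top: int = 6, min_separation_steps: int = 2
) -> WeightVector:
    """Project the discriminant back onto wavenumbers.

    weights = loadings^T . lda_direction, unit-normalized, with the sign
    fixed so the largest-magnitude element is positive.  ``top_features``
    ranks weight-peak clusters by |weight|, requiring peaks to be at least
    ``min_separation_steps`` grid steps apart.
    """
    if model.pca.loadings_ is None:
        raise ValueError("model must be fitted before back-projection")
    w = model.pca.loadings_.T @ model.lda_direction
    norm = np.linalg.norm(w)
    if norm == 0:
        raise ValueError("degenerate discriminant: zero weighting vector")
    w = w / norm
    imax = int(np.argmax(np.abs(w)))
    if w[imax] < 0:
        w = -w
    top = _top_peak_features(model.axis.values, w, n_top, min_separation_steps)
    return WeightVector(model.axis, w, top)


def _top_peak_features(
    wn: np.ndarray, w: np.ndarray, n_top: int, min_separation_steps: int
) -> list[tuple[float, float]]:
    """Rank local maxima ("peak clusters") of |w| by height.

    A broad hump of large weights counts as a single feature; peaks must
    be at least ``min_separation_steps`` grid points apart.
    """
    from scipy.signal import find_peaks

    mag = np.abs(w)
    idx, _ = find_peaks(mag, distance=max(min_separation_steps, 1))
    if idx.size == 0:
        idx = np.array([int(np.argmax(mag))])
    ranked = idx[np.argsort(-mag[idx])][:n_top]
    return [(float(wn[i]), float(mag[i])) for i in ranked]


def lesion_vote(classes: np.ndarray, threshold: float = 0.5) -> str:
    """Majority-vote prognosis: T iff the fraction of spectra predicted T
    is at least the threshold (inclusive)."""
    classes = np.asarray(classes)
    if classes.size == 0:
        raise ValueError("cannot vote on an empty prediction set")
    frac_t = float(np.mean(classes == "T"))
    return "T" if frac_t >= threshold else "NT"


# ---------------------------------------------------------------------------
# LOPOCV evaluation
# ---------------------------------------------------------------------------


def run_lopocv_evaluation(
    cfg: PipelineConfig,
    cohort: Cohort,
    splits: list[CVSplit] | None = None,
    n_per_sample: int | None = 500,
    seed: int = 0,
) -> EvaluationReport:
    """Evaluate a bound pipeline with PCA-LDA under LOPOCV.

    The pipeline's preprocessing (everything before feature extraction) is
    applied with train-only fitting per fold; PCA-LDA is then fitted at the
    pipeline's explained-variance target.  Stateless per-spectrum steps
    are computed once over the pooled cohort for speed — they involve no
    fitting, so this cannot leak test information.
    """
    cfg.validate(require_bound=True)
    if n_per_sample is not None:
        cohort = subsample_balanced(cohort, n_per_sample, seed)
    if splits is None:
        splits = lopocv_splits(cohort)
    ev = cfg.feature_variance if cfg.feature_extraction == "pca" else 90.0

    X, y, rows = _pooled_matrix(cohort)
    wn = cohort.axis.values
    steps = [s for s in build_steps(cfg) if s.name != "feature_extraction:pca"]
    n_prefix = 0
    for st in steps:
        if not st.stateless:
            break
        n_prefix += 1
    for st in steps[:n_prefix]:
        X, wn = st.fn(X, wn)
    remainder = steps[n_prefix:]
    reduced_axis = SpectralAxis(wn) if n_prefix == len(steps) else None

    folds: list[FoldPrediction] = []
    for split in splits:
        tr_idx = np.concatenate([rows[i] for i in split.train_ids])
        Xtr, wn_f = X[tr_idx], wn
        fitted = []
        for st in remainder:
            if st.stateless:
                Xtr, wn_f = st.fn(Xtr, wn_f)
            else:
                est = st.factory(seed).fit(Xtr)
                fitted.append((st, est))
                Xtr = est.transform(Xtr)
        fold_axis = reduced_axis if reduced_axis is not None else SpectralAxis(wn_f)
        model = fit_pca_lda(Xtr, y[tr_idx], fold_axis, explained_variance=ev)

        lesions = {}
        for lid in split.test_pair:
            Xte, wn_t = X[rows[lid]], wn
            for st in remainder:
                if st.stateless:
                    Xte, wn_t = st.fn(Xte, wn_t)
            for st, est in fitted:
                Xte = est.transform(Xte)
            scores, classes, probs = predict_spectra(model, Xte)
            lesions[lid] = {
                "scores": scores,
                "classes": classes,
                "probs": probs,
                "truth": cohort[lid].outcome,
            }
        folds.append(FoldPrediction(split, lesions, backproject_weights(model)))
    return aggregate_report(folds, cohort)


def aggregate_report(folds: list[FoldPrediction], cohort: Cohort) -> EvaluationReport:
    """Aggregate fold predictions into the evaluation report.

    Spectrum-level sensitivity/specificity are computed per fold over the
    held-out pair's spectra and summarised as mean +/- SD across folds (in
    percent).  Lesion-level metrics come from majority votes: each
    lesion's correct-prediction frequency over its test appearances, and
    per-class mean +/- SD of those frequencies.  Lesions wrong in at least
    half their appearances are listed as mislabelled.
    """
    tested = {lid for f in folds for lid in f.lesions}
    missing = [s.lesion_id for s in cohort if s.lesion_id not in tested]
    if missing:
        raise ValueError(
            f"lesions never tested: {missing}; LOPOCV coverage is incomplete"
        )

    sens_f, spec_f = [], []
    correct: dict[str, int] = {s.lesion_id: 0 for s in cohort}
    appearances: dict[str, int] = {s.lesion_id: 0 for s in cohort}
    for f in folds:
        tp = fn = tn = fp = 0
        for lid, rec in f.lesions.items():
            pred_t = rec["classes"] == "T"
            if rec["truth"] == "T":
                tp += int(pred_t.sum())
                fn += int((~pred_t).sum())
            else:
                fp += int(pred_t.sum())
                tn += int((~pred_t).sum())
            vote = lesion_vote(rec["classes"])
            appearances[lid] += 1
            if vote == rec["truth"]:
                correct[lid] += 1
        if tp + fn:
            sens_f.append(100.0 * tp / (tp + fn))
        if tn + fp:
            spec_f.append(100.0 * tn / (tn + fp))

    freq = {lid: correct[lid] / appearances[lid] for lid in appearances}
    t_freq = [freq[s.lesion_id] for s in cohort if s.outcome == "T"]
    nt_freq = [freq[s.lesion_id] for s in cohort if s.outcome == "NT"]
    mislabelled = sorted(lid for lid, fr in freq.items() if fr <= 0.5)

    weights_folds = [f.weighting for f in folds]
    w_mean = _mean_weighting(weights_folds)
    roc = roc_curves(
        [
            (
                np.concatenate([rec["scores"] for rec in f.lesions.values()]),
                np.concatenate(
                    [
                        np.full(rec["scores"].size, 1 if rec["truth"] == "T" else 0)
                        for rec in f.lesions.values()
                    ]
                ),
            )
            for f in folds
        ]
    )

    def msd(v):
        v = np.asarray(v, dtype=float)
        return (float(v.mean()), float(v.std(ddof=1)) if v.size > 1 else 0.0)

    return EvaluationReport(
        sensitivity_spectrum=msd(sens_f),
        specificity_spectrum=msd(spec_f),
        sensitivity_lesion=msd([100 * f_ for f_ in t_freq]),
        specificity_lesion=msd([100 * f_ for f_ in nt_freq]),
        per_lesion_frequency=freq,
        per_lesion_appearances=appearances,
        mislabelled=mislabelled,
        roc=roc,
        weighting_mean=w_mean,
        weighting_folds=weights_folds,
        folds=folds,
    )


def _mean_weighting(weights: list[WeightVector]) -> WeightVector:
    ref = weights[0].weights
    acc = np.zeros_like(ref)
    for wv in weights:
        w = wv.weights
        acc += w if (w @ ref) >= 0 else -w
    acc /= np.linalg.norm(acc)
    imax = int(np.argmax(np.abs(acc)))
    if acc[imax] < 0:
        acc = -acc
    axis = weights[0].axis
    top = _top_peak_features(axis.values, acc, 6, 2)
    return WeightVector(axis, acc, top)


def roc_curves(fold_scores: list[tuple[np.ndarray, np.ndarray]]) -> dict:
    """Vertically averaged ROC over folds on a common 101-point FPR grid.

    Each fold's ROC is computed from its LD scores and linearly
    interpolated onto the grid; the mean and median true-positive rates
    are reported together with per-fold and mean AUC.  Folds whose test
    spectra contain a single class are skipped with a warning.
    """
    tprs, aucs = [], []
    for scores, truth in fold_scores:
        if len(set(np.unique(truth))) < 2:
            warnings.warn("ROC fold skipped: single-class test set")
            continue
        fpr, tpr, _ = roc_curve(truth, scores)
        tprs.append(np.interp(FPR_GRID, fpr, tpr))
        aucs.append(sk_auc(fpr, tpr))
    if not tprs:
        raise ValueError("no fold with both classes; cannot build ROC curves")
    T = np.vstack(tprs)
    return {
        "fpr_grid": FPR_GRID.copy(),
        "tpr_mean": T.mean(axis=0),
        "tpr_median": np.median(T, axis=0),
        "tpr_folds": T,
        "auc_folds": aucs,
        "auc_mean": float(np.mean(aucs)),
    }


def probability_map(
    img: HyperspectralImage,
    model: LDModel,
    state: PipelineState | None = None,
    render_path: str | Path | None = None,
) -> np.ndarray:
    """Per-pixel probability of transformation mapped over the section.

    Pixels with a positive mask label are preprocessed (via the fitted
    pipeline state, if given), scored by the discriminant and assigned
    P(T) in [0, 1]; background pixels are NaN.  Rendering uses a
    red (T) – green (NT) diverging scale on a grey background.
    """
    if img.mask is None:
        raise ValueError("image needs a mask identifying the pixels to score")
    sel = img.mask > 0
    grid = np.full(img.mask.shape, np.nan)
    if sel.any():
        X = img.cube[sel]
        feats = state.transform(X) if state is not None else X
        if feats.shape[1] != model.n_features_in_:
            raise ValueError(
                f"axis mismatch: model expects {model.n_features_in_} features, "
                f"got {feats.shape[1]}"
            )
        _, _, probs = predict_spectra(model, feats)
        grid[sel] = probs
    if render_path is not None:
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 5))
        cmap = plt.get_cmap("RdYlGn_r").copy()
        cmap.set_bad("0.8")
        im = ax.imshow(np.ma.masked_invalid(grid), cmap=cmap, vmin=0, vmax=1)
        fig.colorbar(im, ax=ax, label="P(transformation)")
        ax.set_axis_off()
        fig.savefig(render_path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return grid
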