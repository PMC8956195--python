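"""Spectral preprocessing operators and pipeline configurations.

Implements every preprocessing step of the searched pipeline space as a
pure, composable transform: Savitzky–Golay smoothing and differentiation,
PCA denoising, rubberband (lower convex hull) baseline subtraction,
excision of the paraffin-dominated 1340–1490 cm^-1 region, per-spectrum
normalization (vector / min-max / amide I), per-wavenumber scaling and
PCA feature extraction.

Transforms that learn anything from data (PCA denoise, scalers, feature
PCA) follow fit/apply semantics and are fitted on training folds only;
per-spectrum transforms are stateless and applied identically everywhere.
The canonical step order is smoothing -> baseline -> paraffin excision ->
normalization -> scaling -> feature extraction; order permutation is
supported but off by default (the searched space counts method choices,
not orders).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any

import numpy as np
from scipy.signal import savgol_filter
from sklearn.decomposition import PCA
from sklearn.preprocessing import MinMaxScaler, StandardScaler

from .spectra_core import SpectralAxis, Spectrum

__all__ = [
    "PipelineConfig",
    "PARAFFIN_WINDOW",
    "AMIDE_I_WINDOW",
    "CANONICAL_ORDER",
    "sg_smooth",
    "sg_derivative",
    "rubberband",
    "excise_paraffin",
    "normalize",
    "PCADenoise",
    "fit_scaler",
    "FeaturePCA",
    "fit_feature_pca",
    "apply_pipeline",
    "build_steps",
    "optimal_pipeline",
]

#: Spectral window dominated by embedding-paraffin absorbance, cm^-1 (closed).
PARAFFIN_WINDOW = (1340.0, 1490.0)

#: Amide I protein band window used for amide-I normalization, cm^-1.
AMIDE_I_WINDOW = (1600.0, 1700.0)

CANONICAL_ORDER = (
    "smoothing",
    "baseline",
    "paraffin_excision",
    "normalization",
    "scaling",
    "feature_extraction",
)

_SG_WINDOWS = tuple(range(5, 22, 2))


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """One point of the searched preprocessing/classifier space.

    Categorical method choices follow the searched option table
    (3 smoothing x 3 baseline x 1 excision x 4 normalization x 3 scaling x
    2 feature extraction x 3 classifiers = 648 combinations); hyperparameter
    fields may be ``None`` in an unbound skeleton and are validated against
    their allowed ranges when set.
    """

    smoothing: str = "none"            # sg | pca | none
    sg_window: int | None = None       # odd, 5..21
    sg_polyorder: int | None = None    # 2 | 3
    denoise_variance: float | None = None  # % in [80, 95]

    baseline: str = "none"             # rubberband | sg_diff | none
    diff_window: int | None = None     # odd, 5..21
    diff_polyorder: int | None = None  # 2 | 3
    diff_order: int | None = None      # 1 | 2

    paraffin_lo: float = PARAFFIN_WINDOW[0]
    paraffin_hi: float = PARAFFIN_WINDOW[1]

    normalization: str = "none"        # vector | minmax | amide_i | none
    scaling: str = "none"              # standard | minmax | none
    feature_extraction: str = "none"   # pca | none
    feature_variance: float | None = None  # % in [90, 98]

    classifier: str = "lda"            # logistic | lda | random_forest
    logistic_c: float | None = None    # [0.001, 10]
    rf_max_depth_limited: bool | None = None
    rf_min_samples_split: int | None = None  # 2..5
    rf_min_samples_leaf: int | None = None   # 1 | 2
    rf_bootstrap: bool | None = None

    order: tuple[str, ...] = CANONICAL_ORDER

    def __post_init__(self) -> None:
        self.order = tuple(self.order)
        self.validate()

    def validate(self, require_bound: bool = False) -> None:
        def check(name: str, value: Any, ok: bool) -> None:
            if value is None:
                if require_bound:
                    raise ValueError(f"hyperparameter {name} is unbound")
                return
            if not ok:
                raise ValueError(f"{name}={value!r} outside the allowed options")

        choices = {
            "smoothing": ("sg", "pca", "none"),
            "baseline": ("rubberband", "sg_diff", "none"),
            "normalization": ("vector", "minmax", "amide_i", "none"),
            "scaling": ("standard", "minmax", "none"),
            "feature_extraction": ("pca", "none"),
            "classifier": ("logistic", "lda", "random_forest"),
        }
        for name, opts in choices.items():
            if getattr(self, name) not in opts:
                raise ValueError(
                    f"{name}={getattr(self, name)!r} must be one of {opts}"
                )
        if sorted(self.order) != sorted(CANONICAL_ORDER):
            raise ValueError(f"order must permute {CANONICAL_ORDER}, got {self.order}")
        if self.paraffin_lo >= self.paraffin_hi:
            raise ValueError("paraffin window must satisfy lo < hi")

        if self.smoothing == "sg":
            check("sg_window", self.sg_window, self.sg_window in _SG_WINDOWS)
            check("sg_polyorder", self.sg_polyorder, self.sg_polyorder in (2, 3))
        if self.smoothing == "pca":
            check(
                "denoise_variance",
                self.denoise_variance,
                self.denoise_variance is not None and 80 <= self.denoise_variance <= 95,
            )
        if self.baseline == "sg_diff":
            check("diff_window", self.diff_window, self.diff_window in _SG_WINDOWS)
            check("diff_polyorder", self.diff_polyorder, self.diff_polyorder in (2, 3))
            check("diff_order", self.diff_order, self.diff_order in (1, 2))
            if (
                self.diff_order is not None
                and self.diff_polyorder is not None
                and self.diff_order > self.diff_polyorder
            ):
                raise ValueError("diff_order must not exceed diff_polyorder")
        if self.feature_extraction == "pca":
            check(
                "feature_variance",
                self.feature_variance,
                self.feature_variance is not None and 90 <= self.feature_variance <= 98,
            )
        if self.classifier == "logistic":
            check(
                "logistic_c",
                self.logistic_c,
                self.logistic_c is not None and 0.001 <= self.logistic_c <= 10,
            )
        if self.classifier == "random_forest":
            check(
                "rf_min_samples_split",
                self.rf_min_samples_split,
                self.rf_min_samples_split in (2, 3, 4, 5),
            )
            check(
                "rf_min_samples_leaf",
                self.rf_min_samples_leaf,
                self.rf_min_samples_leaf in (1, 2),
            )

    # -- free hyperparameters -------------------------------------------------

    def free_hyperparameters(self) -> dict[str, dict]:
        """Unbound hyperparameter names with their search domains."""
        space: dict[str, dict] = {}
        if self.smoothing == "sg":
            if self.sg_window is None:
                space["sg_window"] = {"type": "ordinal", "options": _SG_WINDOWS}
            if self.sg_polyorder is None:
                space["sg_polyorder"] = {"type": "ordinal", "options": (2, 3)}
        if self.smoothing == "pca" and self.denoise_variance is None:
            space["denoise_variance"] = {"type": "uniform", "low": 80.0, "high": 95.0}
        if self.baseline == "sg_diff":
            if self.diff_window is None:
                space["diff_window"] = {"type": "ordinal", "options": _SG_WINDOWS}
            if self.diff_polyorder is None:
                space["diff_polyorder"] = {"type": "ordinal", "options": (2, 3)}
            if self.diff_order is None:
                space["diff_order"] = {"type": "ordinal", "options": (1, 2)}
        if self.feature_extraction == "pca" and self.feature_variance is None:
            space["feature_variance"] = {"type": "uniform", "low": 90.0, "high": 98.0}
        if self.classifier == "logistic" and self.logistic_c is None:
            space["logistic_c"] = {"type": "loguniform", "low": 0.001, "high": 10.0}
        if self.classifier == "random_forest":
            if self.rf_max_depth_limited is None:
                space["rf_max_depth_limited"] = {"type": "ordinal", "options": (False, True)}
            if self.rf_min_samples_split is None:
                space["rf_min_samples_split"] = {"type": "ordinal", "options": (2, 3, 4, 5)}
            if self.rf_min_samples_leaf is None:
                space["rf_min_samples_leaf"] = {"type": "ordinal", "options": (1, 2)}
            if self.rf_bootstrap is None:
                space["rf_bootstrap"] = {"type": "ordinal", "options": (False, True)}
        return space

    def bind(self, **params: Any) -> "PipelineConfig":
        cfg = replace(self, **params)
        if self.baseline == "sg_diff" and cfg.diff_order is not None and cfg.diff_polyorder is not None:
            if cfg.diff_order > cfg.diff_polyorder:
                cfg = replace(cfg, diff_order=cfg.diff_polyorder)
        return cfg

    def bind_defaults(self) -> "PipelineConfig":
        """Bind every free hyperparameter to the midpoint of its domain."""
        params = {}
        for name, dom in self.free_hyperparameters().items():
            if dom["type"] == "ordinal":
                opts = dom["options"]
                params[name] = opts[len(opts) // 2]
            elif dom["type"] == "loguniform":
                params[name] = float(np.sqrt(dom["low"] * dom["high"]))
            else:
                params[name] = (dom["low"] + dom["high"]) / 2
        return self.bind(**params)

    @property
    def is_bound(self) -> bool:
        return not self.free_hyperparameters()

    def method_key(self) -> tuple[str, ...]:
        return (
            self.smoothing,
            self.baseline,
            self.normalization,
            self.scaling,
            self.feature_extraction,
            self.classifier,
        )

    # -- serialisation --------------------------------------------------------

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items()}
        d["order"] = list(self.order)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "order" in d:
            d["order"] = tuple(d["order"])
        return cls(**d)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


def optimal_pipeline() -> PipelineConfig:
    """The best-performing preset: SG smoothing (window 15, order 2),
    first-order SG differentiation, paraffin excision, vector
    normalization, PCA at 90% explained variance, LDA."""
    from importlib import resources

    with resources.files("oedftir").joinpath("presets/optimal.json").open() as f:
        return PipelineConfig.from_dict(json.load(f))


# ---------------------------------------------------------------------------
# Stateless per-spectrum transforms (matrix row-wise; Spectrum wrappers below)
# ---------------------------------------------------------------------------


def _as_matrix(x: np.ndarray) -> tuple[np.ndarray, bool]:
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 1:
        return x[None, :], True
    return x, False


def _segments(wn: np.ndarray) -> list[slice]:
    """Contiguous runs of the grid (the paraffin excision leaves a gap)."""
    if wn.size < 2:
        return [slice(0, wn.size)]
    d = np.diff(wn)
    step = np.median(d)
    breaks = np.nonzero(d > 1.5 * step)[0]
    starts = np.concatenate([[0], breaks + 1])
    stops = np.concatenate([breaks + 1, [wn.size]])
    return [slice(int(a), int(b)) for a, b in zip(starts, stops)]


def _rowwise_savgol(
    y: np.ndarray, wn: np.ndarray, window: int, polyorder: int, deriv: int
) -> np.ndarray:
    if window % 2 == 0:
        raise ValueError(f"Savitzky-Golay window must be odd, got {window}")
    if window <= polyorder:
        raise ValueError(
            f"Savitzky-Golay window ({window}) must exceed polyorder ({polyorder})"
        )
    out = np.empty_like(y)
    for seg in _segments(wn):
        n = seg.stop - seg.start
        if n < window:  # segment too short for the window: fit one polynomial
            xs = wn[seg] - wn[seg].mean()
            for i in range(y.shape[0]):
                coef = np.polynomial.polynomial.polyfit(xs, y[i, seg], min(polyorder, n - 1))
                dcoef = np.polynomial.polynomial.polyder(coef, deriv) if deriv else coef
                out[i, seg] = np.polynomial.polynomial.polyval(xs, dcoef)
            continue
        delta = float(wn[seg][1] - wn[seg][0])
        out[:, seg] = savgol_filter(
            y[:, seg], window, polyorder, deriv=deriv, delta=delta, axis=-1, mode="interp"
        )
    return out


def sg_smooth(s: Spectrum, window: int, polyorder: int = 2) -> Spectrum:
    """Savitzky–Golay smoothing: local least-squares polynomial fit.

    Edges are handled by fitting the polynomial over asymmetric windows
    (scipy's ``interp`` mode).
    """
    y = _rowwise_savgol(s.absorbance[None, :], s.axis.values, window, polyorder, 0)
    return Spectrum(s.axis, y[0])


def sg_derivative(s: Spectrum, window: int, polyorder: int, deriv_order: int) -> Spectrum:
    """Savitzky–Golay derivative w.r.t. wavenumber (per cm^-1 scaling)."""
    if deriv_order > polyorder:
        raise ValueError(
            f"derivative order ({deriv_order}) must not exceed polyorder ({polyorder})"
        )
    y = _rowwise_savgol(s.absorbance[None, :], s.axis.values, window, polyorder, deriv_order)
    return Spectrum(s.axis, y[0])


def _lower_hull_baseline(wn: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Lower convex hull of (wn, y), linearly interpolated (monotone chain)."""
    hull: list[int] = []
    for i in range(wn.size):
        while len(hull) >= 2:
            i1, i2 = hull[-2], hull[-1]
            # pop i2 if it lies on/above the chord i1 -> i
            if (y[i2] - y[i1]) * (wn[i] - wn[i1]) >= (y[i] - y[i1]) * (wn[i2] - wn[i1]):
                hull.pop()
            else:
                break
        hull.append(i)
    return np.interp(wn, wn[hull], y[hull])


def rubberband_matrix(y: np.ndarray, wn: np.ndarray) -> np.ndarray:
    if wn.size < 3:
        raise ValueError("rubberband baseline needs at least 3 points")
    y, _ = _as_matrix(y)
    return y - np.vstack([_lower_hull_baseline(wn, row) for row in y])


def rubberband(s: Spectrum) -> Spectrum:
    """Subtract the lower convex hull of the spectrum (rubberband baseline).

    The result is non-negative everywhere and zero at both endpoints, and
    is invariant to adding any affine function of wavenumber to the input.
    """
    return Spectrum(s.axis, rubberband_matrix(s.absorbance, s.axis.values)[0])


def excision_mask(axis: SpectralAxis, lo: float = PARAFFIN_WINDOW[0], hi: float = PARAFFIN_WINDOW[1]) -> np.ndarray:
    """Boolean keep-mask removing grid points in the closed window [lo, hi]."""
    if hi < axis.wn_min or lo > axis.wn_max:
        raise ValueError(
            f"excision window [{lo}, {hi}] lies outside the axis "
            f"[{axis.wn_min}, {axis.wn_max}]"
        )
    wn = axis.values
    return ~((wn >= lo) & (wn <= hi))


def excise_paraffin(
    s: Spectrum, lo: float = PARAFFIN_WINDOW[0], hi: float = PARAFFIN_WINDOW[1]
) -> tuple[Spectrum, np.ndarray]:
    """Remove the paraffin-dominated window; returns the reduced spectrum
    and the boolean keep-mask on the original grid (for re-expansion of
    weighting vectors with a gap)."""
    keep = excision_mask(s.axis, lo, hi)
    reduced = SpectralAxis(s.axis.values[keep])
    return Spectrum(reduced, s.absorbance[keep]), keep


def normalize_matrix(y: np.ndarray, wn: np.ndarray, method: str) -> np.ndarray:
    y, _ = _as_matrix(y)
    if method == "vector":
        norms = np.sqrt(np.sum(y**2, axis=1, keepdims=True))
        if np.any(norms == 0):
            raise ValueError("vector normalization undefined for an all-zero spectrum")
        return y / norms
    if method == "minmax":
        lo = y.min(axis=1, keepdims=True)
        hi = y.max(axis=1, keepdims=True)
        if np.any(hi == lo):
            raise ValueError("min-max normalization undefined for a constant spectrum")
        return (y - lo) / (hi - lo)
    if method == "amide_i":
        sel = (wn >= AMIDE_I_WINDOW[0]) & (wn <= AMIDE_I_WINDOW[1])
        if sel.sum() < 2:
            raise ValueError(
                f"amide I window {AMIDE_I_WINDOW} does not overlap the axis"
            )
        area = np.trapezoid(np.abs(y[:, sel]), wn[sel], axis=1)[:, None]
        if np.any(area == 0):
            raise ValueError("amide I normalization undefined: zero band area")
        return y / area
    raise ValueError(f"unknown normalization method {method!r}")


def normalize(s: Spectrum, method: str) -> Spectrum:
    """Per-spectrum intensity normalization.

    ``vector`` scales to unit sum of squares (cancels thickness),
    ``minmax`` maps to [0, 1], ``amide_i`` divides by the integrated
    absolute absorbance over 1600–1700 cm^-1.
    """
    return Spectrum(s.axis, normalize_matrix(s.absorbance, s.axis.values, method)[0])


# ---------------------------------------------------------------------------
# Fitted transforms
# ---------------------------------------------------------------------------


def _select_n_components(evr: np.ndarray, threshold_pct: float) -> int:
    cum = np.cumsum(evr)
    k = int(np.searchsorted(cum, threshold_pct / 100.0 - 1e-12) + 1)
    return min(k, evr.size)


def _fit_pca_adaptive(X: np.ndarray, threshold_pct: float, cap: int, random_state: int) -> PCA:
    """Fit PCA with just enough components to reach the variance target.

    Starts from a small truncated (randomized) decomposition and enlarges
    it only when the cumulative explained variance falls short — spectra
    are low-rank, so the first attempt almost always suffices.
    """
    n, d = X.shape
    full = min(n - 1, d)
    k = min(max(8, cap // 8), full)
    if k < full:
        pca = PCA(n_components=k, svd_solver="randomized", random_state=random_state).fit(X)
        if pca.explained_variance_ratio_.sum() >= threshold_pct / 100.0:
            return pca
    # probe insufficient: one exact decomposition (covariance route when the
    # sample outnumbers the grid, plain SVD otherwise)
    if n > d:
        return PCA(svd_solver="covariance_eigh").fit(X)
    return PCA(n_components=full).fit(X)


class PCADenoise:
    """Denoise by reconstructing from the fewest principal components whose
    cumulative explained variance reaches the threshold (percent)."""

    def __init__(self, explained_variance: float, max_components: int = 120, random_state: int = 0):
        if not 0 < explained_variance <= 100:
            raise ValueError(
                f"explained_variance must be in (0, 100], got {explained_variance}"
            )
        self.explained_variance = explained_variance
        self.max_components = max_components
        self.random_state = random_state
        self._pca: PCA | None = None
        self.n_components_: int | None = None

    def fit(self, X: np.ndarray) -> "PCADenoise":
        X = np.asarray(X, dtype=np.float64)
        if X.shape[0] < 2:
            raise ValueError("PCA denoising needs at least 2 training spectra")
        pca = _fit_pca_adaptive(X, self.explained_variance, self.max_components, self.random_state)
        self.n_components_ = _select_n_components(
            pca.explained_variance_ratio_, self.explained_variance
        )
        self._pca = pca
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self._pca is None:
            raise RuntimeError("PCADenoise must be fitted before use")
        k = self.n_components_
        scores = (X - self._pca.mean_) @ self._pca.components_[:k].T
        return scores @ self._pca.components_[:k] + self._pca.mean_


def fit_scaler(X: np.ndarray, method: str):
    """Fit a per-wavenumber scaler on training spectra.

    ``standard`` centres to mean 0 / SD 1 (a zero-variance channel maps to
    0); ``minmax`` maps each channel's training range to [0, 1].
    """
    X = np.asarray(X, dtype=np.float64)
    if X.shape[0] < 2:
        raise ValueError("scaler fitting needs at least 2 training spectra")
    if method == "standard":
        return StandardScaler().fit(X)
    if method == "minmax":
        return MinMaxScaler(clip=False).fit(X)
    raise ValueError(f"unknown scaling method {method!r}")


class FeaturePCA:
    """PCA feature extraction keeping the fewest components reaching the
    explained-variance threshold; loadings are retained so discriminant
    weights can be projected back to wavenumbers."""

    def __init__(self, explained_variance: float, max_components: int = 150, random_state: int = 0):
        if not 0 < explained_variance <= 100:
            raise ValueError(
                f"explained_variance must be in (0, 100], got {explained_variance}"
            )
        self.explained_variance = explained_variance
        self.max_components = max_components
        self.random_state = random_state
        self.loadings_: np.ndarray | None = None  # (k, n_wavenumbers)
        self.mean_: np.ndarray | None = None
        self.explained_variance_ratio_: np.ndarray | None = None
        self.component_variances_: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "FeaturePCA":
        X = np.asarray(X, dtype=np.float64)
        if X.shape[0] < 2:
            raise ValueError("feature PCA needs at least 2 training spectra")
        pca = _fit_pca_adaptive(X, self.explained_variance, self.max_components, self.random_state)
        k = _select_n_components(pca.explained_variance_ratio_, self.explained_variance)
        self.loadings_ = pca.components_[:k].copy()
        self.mean_ = pca.mean_.copy()
        self.explained_variance_ratio_ = pca.explained_variance_ratio_[:k].copy()
        self.component_variances_ = pca.explained_variance_[:k].copy()
        return self

    @property
    def n_components_(self) -> int:
        if self.loadings_ is None:
            raise RuntimeError("FeaturePCA must be fitted before use")
        return self.loadings_.shape[0]

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.loadings_ is None:
            raise RuntimeError("FeaturePCA must be fitted before use")
        return (np.asarray(X) - self.mean_) @ self.loadings_.T

    def inverse_transform(self, scores: np.ndarray) -> np.ndarray:
        return np.asarray(scores) @ self.loadings_ + self.mean_


def fit_feature_pca(X: np.ndarray, explained_variance: float = 90.0) -> FeaturePCA:
    return FeaturePCA(explained_variance).fit(X)


# ---------------------------------------------------------------------------
# Pipeline assembly
# ---------------------------------------------------------------------------


@dataclass
class _Step:
    name: str
    stateless: bool
    # stateless: fn(y, wn) -> (y, wn); stateful: factory(seed) -> estimator
    fn: Any = None
    factory: Any = None


def build_steps(cfg: PipelineConfig) -> list[_Step]:
    """Expand a bound configuration into its ordered preprocessing steps.

    Stateless steps are pure row-wise functions of the matrix and current
    grid; stateful steps are fitted on the training fold only.
    """
    cfg.validate(require_bound=True)
    steps: list[_Step] = []
    for name in cfg.order:
        if name == "smoothing":
            if cfg.smoothing == "sg":
                w, p = cfg.sg_window, cfg.sg_polyorder
                steps.append(
                    _Step("smoothing:sg", True, fn=lambda y, wn, w=w, p=p: (_rowwise_savgol(y, wn, w, p, 0), wn))
                )
            elif cfg.smoothing == "pca":
                v = cfg.denoise_variance
                steps.append(
                    _Step("smoothing:pca", False, factory=lambda seed, v=v: PCADenoise(v, random_state=seed))
                )
        elif name == "baseline":
            if cfg.baseline == "rubberband":
                steps.append(
                    _Step("baseline:rubberband", True, fn=lambda y, wn: (rubberband_matrix(y, wn), wn))
                )
            elif cfg.baseline == "sg_diff":
                w, p, d = cfg.diff_window, cfg.diff_polyorder, cfg.diff_order
                steps.append(
                    _Step(
                        "baseline:sg_diff",
                        True,
                        fn=lambda y, wn, w=w, p=p, d=d: (_rowwise_savgol(y, wn, w, p, d), wn),
                    )
                )
        elif name == "paraffin_excision":
            lo, hi = cfg.paraffin_lo, cfg.paraffin_hi

            def _excise(y, wn, lo=lo, hi=hi):
                keep = ~((wn >= lo) & (wn <= hi))
                return y[:, keep], wn[keep]

            steps.append(_Step("paraffin_excision", True, fn=_excise))
        elif name == "normalization":
            if cfg.normalization != "none":
                m = cfg.normalization
                steps.append(
                    _Step(f"normalization:{m}", True, fn=lambda y, wn, m=m: (normalize_matrix(y, wn, m), wn))
                )
        elif name == "scaling":
            if cfg.scaling != "none":
                m = cfg.scaling
                steps.append(
                    _Step(f"scaling:{m}", False, factory=lambda seed, m=m: _ScalerStep(m))
                )
        elif name == "feature_extraction":
            if cfg.feature_extraction == "pca":
                v = cfg.feature_variance
                steps.append(
                    _Step("feature_extraction:pca", False, factory=lambda seed, v=v: FeaturePCA(v, random_state=seed))
                )
    return steps


class _ScalerStep:
    def __init__(self, method: str):
        self.method = method
        self._scaler = None

    def fit(self, X: np.ndarray) -> "_ScalerStep":
        self._scaler = fit_scaler(X, self.method)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return self._scaler.transform(X)


@dataclass
class PipelineState:
    """Everything fitted while applying a pipeline to a training fold."""

    cfg: PipelineConfig
    axis_in: SpectralAxis
    wn_out: np.ndarray
    fitted: dict[str, Any]
    keep_mask: np.ndarray  # excision keep-mask on the input grid
    feature_pca: FeaturePCA | None

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Apply the full fitted pipeline to new spectra on the input axis."""
        y = np.atleast_2d(np.asarray(X, dtype=np.float64))
        wn = self.axis_in.values
        for step in build_steps(self.cfg):
            if step.stateless:
                y, wn = step.fn(y, wn)
            else:
                y = self.fitted[step.name].transform(y)
        return y


def apply_pipeline(
    cfg: PipelineConfig,
    train: np.ndarray,
    test: np.ndarray | None,
    axis: SpectralAxis,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray | None, PipelineState]:
    """Run the preprocessing chain, fitting data-dependent steps on train only.

    Returns transformed train features, test features (or None) and the
    fitted :class:`PipelineState`.  Errors raised inside a step are
    annotated with the step name.
    """
    y_tr = np.atleast_2d(np.asarray(train, dtype=np.float64))
    y_te = None if test is None else np.atleast_2d(np.asarray(test, dtype=np.float64))
    wn = axis.values
    if y_tr.shape[1] != wn.size or (y_te is not None and y_te.shape[1] != wn.size):
        raise ValueError("train/test matrices must share the pipeline's axis")
    fitted: dict[str, Any] = {}
    feature_pca: FeaturePCA | None = None
    for step in build_steps(cfg):
        try:
            if step.stateless:
                y_tr, wn_new = step.fn(y_tr, wn)
                if y_te is not None:
                    y_te, _ = step.fn(y_te, wn)
                wn = wn_new
            else:
                est = step.factory(seed).fit(y_tr)
                fitted[step.name] = est
                y_tr = est.transform(y_tr)
                if y_te is not None:
                    y_te = est.transform(y_te)
                if isinstance(est, FeaturePCA):
                    feature_pca = est
        except Exception as exc:
            raise type(exc)(f"[step {step.name}] {exc}") from exc
    keep = excision_mask(axis, cfg.paraffin_lo, cfg.paraffin_hi)
    state = PipelineState(cfg, axis, wn, fitted, keep, feature_pca)
    return y_tr, y_te, state
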