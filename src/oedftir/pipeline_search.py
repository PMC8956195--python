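"""Objective optimization of the preprocessing/classifier pipeline space.

The searched space is the Cartesian product of method choices per step
(3 smoothing x 3 baseline x 1 paraffin excision x 4 normalization x
3 scaling x 2 feature extraction x 3 classifiers = 648 combinations).
Each combination ("skeleton") has its hyperparameters tuned by a
sequential model-based (Bayesian) optimizer maximizing the mean Matthews
correlation coefficient (MCC) under leave-one-pair-out cross-validation
(LOPOCV): every (transforming, non-transforming) lesion pair serves once
as the test set, giving n_T x n_NT folds — 70 folds for the 10 T + 7 NT
cohort, each training on 9 T + 6 NT lesions.  Equal numbers of spectra
(default 500) are drawn from each lesion to avoid size-related bias.

Fold MCC is computed over the pooled spectra of the held-out pair (two
lesions give too few lesion-level outcomes for a per-fold MCC).  The
surrogate model is a Gaussian process (Matern kernel) with expected-
improvement acquisition over a unit-cube encoding of the hyperparameters;
ordinal parameters are encoded on an evenly spaced grid and the logistic
regularisation strength on a log scale.
"""

from __future__ import annotations

import itertools
import math
import warnings
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
from joblib import Parallel, delayed
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern
from sklearn.linear_model import LogisticRegression

from .preprocessing import PipelineConfig, build_steps
from .spectra_core import Cohort, LesionSample

__all__ = [
    "CVSplit",
    "SearchResult",
    "DEFAULT_SPACE",
    "enumerate_pipelines",
    "lopocv_splits",
    "subsample_balanced",
    "mcc",
    "evaluate_pipeline",
    "bayes_optimize",
    "search_all",
    "plot_rank_curve",
]

#: The searched method options per step; the product over steps gives the
#: 648 pipeline combinations.
DEFAULT_SPACE: dict[str, tuple[str, ...]] = {
    "smoothing": ("sg", "pca", "none"),
    "baseline": ("rubberband", "sg_diff", "none"),
    "paraffin_excision": ("excise",),
    "normalization": ("vector", "minmax", "amide_i", "none"),
    "scaling": ("standard", "minmax", "none"),
    "feature_extraction": ("pca", "none"),
    "classifier": ("logistic", "lda", "random_forest"),
}


@dataclass(frozen=True)
class CVSplit:
    """One leave-one-pair-out fold: a (T, NT) test pair and the rest."""

    test_pair: tuple[str, str]
    train_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if set(self.test_pair) & set(self.train_ids):
            raise ValueError("test lesions must not appear in the training set")


@dataclass
class SearchResult:
    """Best configuration found for one skeleton plus its CV record."""

    pipeline: PipelineConfig
    mean_mcc: float
    per_fold_mcc: list[float]
    n_evaluations: int
    seed: int
    history: list[tuple[dict, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.per_fold_mcc and not math.isclose(
            self.mean_mcc, float(np.mean(self.per_fold_mcc)), abs_tol=1e-9
        ):
            raise ValueError("mean_mcc must equal the mean of per_fold_mcc")


def enumerate_pipelines(space: dict[str, tuple[str, ...]] | None = None) -> list[PipelineConfig]:
    """Cartesian product of method options per step, hyperparameters unbound."""
    space = dict(DEFAULT_SPACE if space is None else space)
    for step, opts in space.items():
        if not opts:
            raise ValueError(f"step {step!r} lists no options")
    steps = ["smoothing", "baseline", "paraffin_excision", "normalization",
             "scaling", "feature_extraction", "classifier"]
    for s in steps:
        space.setdefault(s, DEFAULT_SPACE[s])
    skeletons = []
    for combo in itertools.product(*(space[s] for s in steps)):
        kw = dict(zip(steps, combo))
        kw.pop("paraffin_excision")  # always on, single option
        skeletons.append(PipelineConfig(**kw))
    return skeletons


def lopocv_splits(cohort: Cohort) -> list[CVSplit]:
    """One fold per (T, NT) lesion pair; training on all remaining lesions."""
    cohort.require_both_classes()
    t_ids, nt_ids = cohort.ids("T"), cohort.ids("NT")
    if len(t_ids) + len(nt_ids) < 3:
        raise ValueError(
            "LOPOCV needs at least 3 lesions so every fold has a non-empty "
            "training set"
        )
    all_ids = set(t_ids) | set(nt_ids)
    return [
        CVSplit((t, nt), tuple(sorted(all_ids - {t, nt})))
        for t in t_ids
        for nt in nt_ids
    ]


def _lesion_rng(seed: int, lesion_id: str) -> np.random.Generator:
    return np.random.default_rng([seed, zlib.crc32(lesion_id.encode())])


def subsample_balanced(cohort: Cohort, n_per_sample: int = 500, seed: int = 0) -> Cohort:
    """Draw exactly ``n_per_sample`` spectra per lesion (seeded, uniform).

    Lesions smaller than ``n_per_sample`` are sampled with replacement so
    desk-scale synthetic cohorts still yield balanced counts.
    """
    samples = []
    for s in cohort:
        rng = _lesion_rng(seed, s.lesion_id)
        replace_ = s.n_spectra < n_per_sample
        idx = rng.choice(s.n_spectra, size=n_per_sample, replace=replace_)
        if not replace_:
            idx = np.sort(idx)
        samples.append(
            LesionSample(s.lesion_id, s.outcome, s.absorbance[idx], s.axis, s.meta)
        )
    return Cohort(samples)


def mcc(tp: int, fp: int, tn: int, fn: int) -> float:
    """Matthews correlation coefficient from confusion counts.

    (tp*tn - fp*fn) / sqrt((tp+fp)(tp+fn)(tn+fp)(tn+fn)); if any factor of
    the denominator is zero the coefficient is 0 by convention.
    """
    counts = (tp, fp, tn, fn)
    if any(c < 0 for c in counts):
        raise ValueError(f"confusion counts must be non-negative, got {counts}")
    if sum(counts) == 0:
        raise ValueError("confusion table is empty")
    denom = math.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    if denom == 0:
        return 0.0
    return (float(tp) * tn - float(fp) * fn) / denom


def make_classifier(cfg: PipelineConfig, seed: int):
    """Instantiate the configured classifier (fold-level, seeded)."""
    if cfg.classifier == "logistic":
        return LogisticRegression(C=cfg.logistic_c, max_iter=2000)
    if cfg.classifier == "lda":
        return LinearDiscriminantAnalysis()
    if cfg.classifier == "random_forest":
        return RandomForestClassifier(
            n_estimators=100,
            max_depth=10 if cfg.rf_max_depth_limited else None,
            min_samples_split=cfg.rf_min_samples_split,
            min_samples_leaf=cfg.rf_min_samples_leaf,
            bootstrap=cfg.rf_bootstrap,
            random_state=seed,
            n_jobs=1,
        )
    raise ValueError(f"unknown classifier {cfg.classifier!r}")


def _pooled_matrix(cohort: Cohort):
    rows = {}
    mats, labels = [], []
    start = 0
    for s in cohort:
        mats.append(s.absorbance)
        labels.append(np.full(s.n_spectra, 1 if s.outcome == "T" else 0))
        rows[s.lesion_id] = np.arange(start, start + s.n_spectra)
        start += s.n_spectra
    return np.vstack(mats), np.concatenate(labels), rows


def evaluate_pipeline(
    cfg: PipelineConfig, cohort: Cohort, splits: list[CVSplit], seed: int = 0
) -> SearchResult:
    """Mean LOPOCV MCC of one fully bound pipeline configuration.

    Per-spectrum (stateless) preprocessing is computed once over the
    pooled cohort matrix; data-dependent steps and the classifier are
    refitted on each fold's training lesions only, so no test information
    leaks into any fit.  A fold where the classifier fails scores 0 with a
    warning rather than aborting the search.
    """
    cfg.validate(require_bound=True)
    X, y, rows = _pooled_matrix(cohort)
    wn = cohort.axis.values

    steps = build_steps(cfg)
    n_prefix = 0
    for st in steps:
        if not st.stateless:
            break
        n_prefix += 1
    for st in steps[:n_prefix]:
        X, wn = st.fn(X, wn)
    remainder = steps[n_prefix:]

    per_fold: list[float] = []
    for split in splits:
        if set(split.test_pair) & set(split.train_ids):
            raise AssertionError("corrupt split: test lesion in training set")
        tr_idx = np.concatenate([rows[i] for i in split.train_ids])
        te_idx = np.concatenate([rows[i] for i in split.test_pair])
        try:
            Xtr, Xte = X[tr_idx], X[te_idx]
            wn_f = wn
            for st in remainder:
                if st.stateless:
                    Xtr, wn_new = st.fn(Xtr, wn_f)
                    Xte, _ = st.fn(Xte, wn_f)
                    wn_f = wn_new
                else:
                    est = st.factory(seed).fit(Xtr)
                    Xtr, Xte = est.transform(Xtr), est.transform(Xte)
            clf = make_classifier(cfg, seed)
            clf.fit(Xtr, y[tr_idx])
            pred = clf.predict(Xte)
            truth = y[te_idx]
            tp = int(np.sum((pred == 1) & (truth == 1)))
            fp = int(np.sum((pred == 1) & (truth == 0)))
            tn = int(np.sum((pred == 0) & (truth == 0)))
            fn = int(np.sum((pred == 0) & (truth == 1)))
            per_fold.append(mcc(tp, fp, tn, fn))
        except Exception as exc:  # robustness: a failing fold scores 0
            warnings.warn(
                f"fold {split.test_pair}: classifier failed ({exc}); MCC set to 0"
            )
            per_fold.append(0.0)
    return SearchResult(cfg, float(np.mean(per_fold)), per_fold, 1, seed)


# ---------------------------------------------------------------------------
# Sequential model-based hyperparameter optimization
# ---------------------------------------------------------------------------


def _encode(space: dict[str, dict], params: dict) -> np.ndarray:
    x = []
    for name, dom in space.items():
        v = params[name]
        if dom["type"] == "ordinal":
            opts = list(dom["options"])
            x.append(opts.index(v) / max(len(opts) - 1, 1))
        elif dom["type"] == "loguniform":
            lo, hi = math.log(dom["low"]), math.log(dom["high"])
            x.append((math.log(v) - lo) / (hi - lo))
        else:
            x.append((v - dom["low"]) / (dom["high"] - dom["low"]))
    return np.array(x)


def _sample_params(space: dict[str, dict], rng: np.random.Generator) -> dict:
    params = {}
    for name, dom in space.items():
        if dom["type"] == "ordinal":
            opts = dom["options"]
            params[name] = opts[int(rng.integers(len(opts)))]
        elif dom["type"] == "loguniform":
            params[name] = float(
                math.exp(rng.uniform(math.log(dom["low"]), math.log(dom["high"])))
            )
        else:
            params[name] = float(rng.uniform(dom["low"], dom["high"]))
    return params


def bayes_optimize(
    skeleton: PipelineConfig,
    cohort: Cohort,
    splits: list[CVSplit],
    budget: int = 25,
    seed: int = 0,
    n_initial: int | None = None,
) -> SearchResult:
    """Tune a skeleton's free hyperparameters by GP-based optimization.

    Runs ``budget`` CV evaluations: an initial random design followed by
    expected-improvement proposals from a Gaussian-process surrogate over
    the encoded hyperparameter cube.  A skeleton without free
    hyperparameters reduces to a single :func:`evaluate_pipeline` call.
    Every evaluation is logged in ``history``.
    """
    if budget < 1:
        raise ValueError(f"budget must be >= 1, got {budget}")
    space = skeleton.free_hyperparameters()
    if not space:
        res = evaluate_pipeline(skeleton, cohort, splits, seed)
        res.history = [({}, res.mean_mcc)]
        return res

    rng = np.random.default_rng(seed)
    if n_initial is None:
        n_initial = min(budget, max(3, budget // 3))
    history: list[tuple[dict, float]] = []
    X_obs: list[np.ndarray] = []
    y_obs: list[float] = []
    best: SearchResult | None = None

    def run(params: dict) -> None:
        nonlocal best
        cfg = skeleton.bind(**params)
        res = evaluate_pipeline(cfg, cohort, splits, seed)
        history.append((params, res.mean_mcc))
        X_obs.append(_encode(space, params))
        y_obs.append(res.mean_mcc)
        if best is None or res.mean_mcc > best.mean_mcc:
            best = res

    for _ in range(min(n_initial, budget)):
        run(_sample_params(space, rng))

    while len(history) < budget:
        gp = GaussianProcessRegressor(
            kernel=Matern(length_scale=0.3, nu=2.5),
            alpha=1e-4,
            normalize_y=True,
            random_state=int(rng.integers(2**31 - 1)),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gp.fit(np.vstack(X_obs), np.array(y_obs))
        cands = [_sample_params(space, rng) for _ in range(256)]
        Xc = np.vstack([_encode(space, p) for p in cands])
        mu, sd = gp.predict(Xc, return_std=True)
        y_best = max(y_obs)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (mu - y_best) / sd
            from scipy.stats import norm

            ei = (mu - y_best) * norm.cdf(z) + sd * norm.pdf(z)
        ei[sd == 0] = 0.0
        run(cands[int(np.argmax(ei))])

    assert best is not None
    best.n_evaluations = len(history)
    best.history = history
    return best


def _skeleton_seed(master_seed: int, skeleton: PipelineConfig) -> int:
    key = ":".join(skeleton.method_key())
    return (zlib.crc32(f"{master_seed}:{key}".encode()) ^ master_seed) % (2**31 - 1)


def search_all(
    space: dict[str, tuple[str, ...]] | None,
    cohort: Cohort,
    budget_per_pipeline: int = 25,
    seed: int = 0,
    n_per_sample: int = 500,
    n_jobs: int = 1,
    splits: list[CVSplit] | None = None,
    orders: list[tuple[str, ...]] | None = None,
) -> list[SearchResult]:
    """Optimize every pipeline skeleton and rank them by mean LOPOCV MCC.

    Per-skeleton seeds are derived from the master seed by stable hashing
    of the skeleton's method key, so results do not depend on execution
    order and the whole search is deterministic given (cohort, seed,
    budget).  A skeleton whose optimization fails outright is skipped with
    a warning.

    ``orders`` optionally adds step-sequence permutations as an extra,
    off-by-default search dimension: each listed order (a permutation of
    the canonical preprocessing steps) is crossed with every skeleton.
    The default searches method choices only, which is what the
    648-combination count reflects.
    """
    skeletons = enumerate_pipelines(space)
    if orders:
        skeletons = [
            replace(skel, order=tuple(o)) for skel in skeletons for o in orders
        ]
    sub = subsample_balanced(cohort, n_per_sample, seed)
    if splits is None:
        splits = lopocv_splits(sub)

    def one(skel: PipelineConfig) -> SearchResult | None:
        try:
            return bayes_optimize(
                skel, sub, splits, budget_per_pipeline, _skeleton_seed(seed, skel)
            )
        except Exception as exc:
            warnings.warn(f"skeleton {skel.method_key()}: optimization failed ({exc})")
            return None

    results = Parallel(n_jobs=n_jobs)(delayed(one)(s) for s in skeletons)
    ranked = [r for r in results if r is not None]
    ranked.sort(key=lambda r: (-r.mean_mcc, ":".join(r.pipeline.method_key())))
    return ranked


def plot_rank_curve(results: list[SearchResult], path=None, ax=None):
    """Mean MCC per pipeline plotted in descending rank order."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    mccs = [r.mean_mcc for r in results]
    ax.plot(np.arange(1, len(mccs) + 1), mccs, ".-", ms=3)
    ax.axhline(0.0, color="grey", lw=0.7)
    ax.set_xlabel("pipeline rank")
    ax.set_ylabel("mean LOPOCV MCC")
    ax.set_title("Pipeline search: ranked mean MCC")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
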