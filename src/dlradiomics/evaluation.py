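"""Model evaluation: 0.632+ bootstrap AUC, forward selection, the 5x5 model
grid, the corrected resampled paired t-test and imbalance-aware threshold
sweeps.

The central estimator blends the optimistic apparent AUC (train and test on
the full sample X) with the pessimistic out-of-bag AUC (train on a bootstrap
resample X*b, test on the samples left out of it):

    AUC_0.632+ = (1/B) sum_b [ (1 - a(b)) AUC(X,X) + a(b) AUC'(X*b, X*b(0)) ]

with AUC' = max{0.5, AUC_oob}, a(b) = 0.632 / (1 - 0.368 R(b)), and the
relative overfitting rate R(b) equal to 1 when AUC_oob <= 0.5, to
(AUC_app - AUC_oob) / (AUC_app - 0.5) when AUC_app > AUC_oob > 0.5, and 0
otherwise.  Replicates whose in-bag or out-of-bag set contains a single
class are skipped and counted; the apparent AUC is computed once per feature
subset since it does not depend on the replicate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .features import FeatureMatrix
from .models import ClassifierSpec, fit

__all__ = [
    "BootstrapConfig", "BootstrapReplicate", "Auc632Result", "ModelGridResult",
    "TTestResult", "auc", "bootstrap_replicates", "weight_632plus",
    "overfitting_rate", "auc632plus", "forward_select", "evaluate_grid",
    "corrected_resampled_ttest", "undersample_sweep", "volume_correlation_check",
]


@dataclass(frozen=True)
class BootstrapConfig:
    n_bootstrap: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")


@dataclass
class BootstrapReplicate:
    in_bag: np.ndarray
    oob: np.ndarray
    auc_oob: float = float("nan")
    auc_clamped: float = float("nan")
    overfit_rate: float = float("nan")
    weight: float = float("nan")
    value: float = float("nan")
    skipped: bool = False


@dataclass
class Auc632Result:
    auc: float
    sensitivity: float
    specificity: float
    apparent_auc: float
    features: list[str]
    n_bootstrap: int
    n_skipped: int
    replicates: list[BootstrapReplicate] = field(repr=False, default_factory=list)


@dataclass
class ModelGridResult:
    rankers: list[str]
    classifiers: list[str]
    auc_grid: np.ndarray  # (n_rankers, n_classifiers)
    sens_grid: np.ndarray
    spec_grid: np.ndarray
    selected_features: dict
    mean_auc: float
    sd_auc: float


@dataclass
class TTestResult:
    t: float
    df: int
    p_one_tailed: float
    train_test_ratio: float
    degenerate: bool = False


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann–Whitney AUC: P(score_pos > score_neg) with ties counted 1/2."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    pos = scores[y == 1]
    neg = scores[y == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes required to compute AUC")
    # rank-based computation: O((n_pos + n_neg) log n), ties handled via midranks
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def bootstrap_replicates(n: int, cfg: BootstrapConfig | None = None) -> list[BootstrapReplicate]:
    """B in-bag/out-of-bag index splits, reproducible from the master seed."""
    cfg = cfg or BootstrapConfig()
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(cfg.seed)
    reps = []
    for _ in range(cfg.n_bootstrap):
        in_bag = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), in_bag)
        reps.append(BootstrapReplicate(in_bag=in_bag, oob=oob))
    return reps


def weight_632plus(overfit_rate: float) -> float:
    """Replicate weight a(b) = 0.632 / (1 - 0.368 R(b))."""
    return 0.632 / (1.0 - 0.368 * overfit_rate)


def overfitting_rate(auc_apparent: float, auc_oob: float) -> float:
    """Relative overfitting rate R(b) from apparent and out-of-bag AUC."""
    if auc_oob <= 0.5:
        return 1.0
    if auc_apparent > auc_oob > 0.5:
        return (auc_apparent - auc_oob) / (auc_apparent - 0.5)
    return 0.0


def _sens_spec(scores: np.ndarray, y: np.ndarray, threshold: float) -> tuple[float, float]:
    pred = scores > threshold
    pos = y == 1
    sens = float(pred[pos].mean()) if pos.any() else float("nan")
    spec = float((~pred[~pos]).mean()) if (~pos).any() else float("nan")
    return sens, spec


def auc632plus(
    x: np.ndarray,
    y: np.ndarray,
    spec: ClassifierSpec,
    features: list[str] | None = None,
    cfg: BootstrapConfig | None = None,
    replicates: list[BootstrapReplicate] | None = None,
    feature_matrix: FeatureMatrix | None = None,
    keep_replicates: bool = False,
) -> Auc632Result:
    """0.632+ bootstrap AUC (plus sensitivity/specificity) for one model.

    ``x`` may be a plain array or come from ``feature_matrix.subset(features)``.
    Precomputed ``replicates`` can be shared across calls (common random
    numbers for forward selection).  Sensitivity and specificity are blended
    with the same (1-a(b))/a(b) weights, at the classifier's default
    operating point.
    """
    cfg = cfg or BootstrapConfig()
    if feature_matrix is not None:
        names = features if features is not None else list(feature_matrix.feature_names)
        x = feature_matrix.subset(names).values
    else:
        names = list(features) if features is not None else [f"f{j}" for j in range(np.asarray(x).shape[1])]
    x = np.asarray(x, dtype=float)
    y = np.asarray(y).astype(int)
    if x.shape[1] == 0:
        raise ValueError("feature subset must be non-empty")
    if np.unique(y).size < 2:
        raise ValueError("both classes required")
    if replicates is None:
        replicates = bootstrap_replicates(len(y), cfg)

    full_model = fit(spec, x, y)
    app_scores = full_model.predict_scores(x)
    auc_app = auc(app_scores, y)
    thr = full_model.default_threshold
    sens_app, spec_app = _sens_spec(app_scores, y, thr)

    values, sens_vals, spec_vals = [], [], []
    kept_reps = []
    n_skipped = 0
    for rep in replicates:
        yb = y[rep.in_bag]
        if rep.oob.size == 0 or np.unique(yb).size < 2 or np.unique(y[rep.oob]).size < 2:
            n_skipped += 1
            if keep_replicates:
                kept_reps.append(BootstrapReplicate(rep.in_bag, rep.oob, skipped=True))
            continue
        try:
            model = fit(spec, x[rep.in_bag], yb)
            oob_scores = model.predict_scores(x[rep.oob])
        except Exception:  # degenerate in-bag (e.g. zero within-class variance)
            n_skipped += 1
            if keep_replicates:
                kept_reps.append(BootstrapReplicate(rep.in_bag, rep.oob, skipped=True))
            continue
        auc_oob = auc(oob_scores, y[rep.oob])
        auc_clamped = max(0.5, auc_oob)
        r_b = overfitting_rate(auc_app, auc_oob)
        a_b = weight_632plus(r_b)
        value = (1.0 - a_b) * auc_app + a_b * auc_clamped
        values.append(value)
        s_oob, sp_oob = _sens_spec(oob_scores, y[rep.oob], model.default_threshold)
        if np.isfinite(s_oob) and np.isfinite(sens_app):
            sens_vals.append((1.0 - a_b) * sens_app + a_b * s_oob)
        if np.isfinite(sp_oob) and np.isfinite(spec_app):
            spec_vals.append((1.0 - a_b) * spec_app + a_b * sp_oob)
        if keep_replicates:
            kept_reps.append(BootstrapReplicate(
                rep.in_bag, rep.oob, auc_oob=auc_oob, auc_clamped=auc_clamped,
                overfit_rate=r_b, weight=a_b, value=value,
            ))
    if not values:
        raise ValueError("all bootstrap replicates were degenerate")
    return Auc632Result(
        auc=float(np.mean(values)),
        sensitivity=float(np.mean(sens_vals)) if sens_vals else float("nan"),
        specificity=float(np.mean(spec_vals)) if spec_vals else float("nan"),
        apparent_auc=auc_app,
        features=names,
        n_bootstrap=len(values),
        n_skipped=n_skipped,
        replicates=kept_reps,
    )


def forward_select(
    x: np.ndarray,
    y: np.ndarray,
    spec: ClassifierSpec,
    candidate_features: list[str],
    cfg: BootstrapConfig | None = None,
    feature_matrix: FeatureMatrix | None = None,
) -> Auc632Result:
    """Greedy forward selection maximizing the 0.632+ AUC.

    All candidate subsets are evaluated on the same bootstrap splits (common
    random numbers), so the procedure is deterministic given the master seed.
    A step is accepted only on strict improvement of the estimate.
    """
    if not candidate_features:
        raise ValueError("candidate feature list is empty")
    cfg = cfg or BootstrapConfig()
    if feature_matrix is None:
        x = np.asarray(x, dtype=float)
        feature_matrix = FeatureMatrix(
            x, [f"f{j}" for j in range(x.shape[1])],
            [str(i) for i in range(x.shape[0])],
        )
    y = np.asarray(y).astype(int)
    replicates = bootstrap_replicates(len(y), cfg)
    selected: list[str] = []
    best: Auc632Result | None = None
    remaining = list(candidate_features)
    while remaining:
        step_best = None
        step_feat = None
        for name in remaining:
            res = auc632plus(
                None, y, spec, features=selected + [name], cfg=cfg,
                replicates=replicates, feature_matrix=feature_matrix,
            )
            if step_best is None or res.auc > step_best.auc:
                step_best, step_feat = res, name
        if best is not None and step_best.auc <= best.auc:
            break
        best = step_best
        selected.append(step_feat)
        remaining.remove(step_feat)
    return best


def evaluate_grid(
    feature_matrix: FeatureMatrix,
    y: np.ndarray,
    ranker_top_features: dict[str, list[str]],
    classifier_specs: list[ClassifierSpec],
    cfg: BootstrapConfig | None = None,
) -> ModelGridResult:
    """Forward-selected 0.632+ results for every (ranker, classifier) cell."""
    cfg = cfg or BootstrapConfig()
    rankers = list(ranker_top_features)
    classifiers = [s.algorithm for s in classifier_specs]
    shape = (len(rankers), len(classifiers))
    auc_grid = np.full(shape, np.nan)
    sens_grid = np.full(shape, np.nan)
    spec_grid = np.full(shape, np.nan)
    selected = {}
    for i, rk in enumerate(rankers):
        for j, cspec in enumerate(classifier_specs):
            try:
                res = forward_select(None, y, cspec, ranker_top_features[rk],
                                     cfg=cfg, feature_matrix=feature_matrix)
            except ValueError as exc:
                warnings.warn(f"grid cell ({rk}, {cspec.algorithm}) failed: {exc}")
                continue
            auc_grid[i, j] = res.auc
            sens_grid[i, j] = res.sensitivity
            spec_grid[i, j] = res.specificity
            selected[(rk, cspec.algorithm)] = res.features
    done = np.isfinite(auc_grid)
    if not done.all():
        warnings.warn(f"{int((~done).sum())} grid cell(s) failed; mean over completed cells")
    return ModelGridResult(
        rankers=rankers,
        classifiers=classifiers,
        auc_grid=auc_grid,
        sens_grid=sens_grid,
        spec_grid=spec_grid,
        selected_features=selected,
        mean_auc=float(np.nanmean(auc_grid)),
        sd_auc=float(np.nanstd(auc_grid, ddof=1)) if done.sum() > 1 else 0.0,
    )


def corrected_resampled_ttest(diffs: np.ndarray, n_train: float, n_test: float) -> TTestResult:
    """Corrected resampled paired t-test (one-tailed, upper).

    t = mean(d) / sqrt((1/K + n_test/n_train) * s_d^2) with s_d^2 the n-1
    sample variance of the K paired differences; df = K - 1.  The correction
    factor n_test/n_train inflates the variance to account for overlapping
    resamples; with bootstrap resampling the average train/test sizes are used.
    """
    d = np.asarray(diffs, dtype=float)
    k = d.size
    if k < 2:
        raise ValueError("need at least 2 paired differences")
    ratio = n_test / n_train
    s2 = d.var(ddof=1)
    mean = d.mean()
    if s2 == 0:
        if mean == 0:
            return TTestResult(t=0.0, df=k - 1, p_one_tailed=0.5, train_test_ratio=ratio)
        t = np.inf if mean > 0 else -np.inf
        return TTestResult(t=float(t), df=k - 1,
                           p_one_tailed=0.0 if mean > 0 else 1.0,
                           train_test_ratio=ratio, degenerate=True)
    t = mean / np.sqrt((1.0 / k + ratio) * s2)
    p = float(stats.t.sf(t, df=k - 1))
    return TTestResult(t=float(t), df=k - 1, p_one_tailed=p, train_test_ratio=ratio)


def undersample_sweep(
    rates: np.ndarray,
    thresholds: list[float],
    feature_matrix: FeatureMatrix,
    spec: ClassifierSpec,
    candidate_features: list[str] | None = None,
    cfg: BootstrapConfig | None = None,
    n_undersample: int = 100,
    seed: int = 0,
) -> dict[float, float]:
    """Mean 0.632+ AUC per regression-rate threshold under class balancing.

    Each threshold relabels the cohort (rate > threshold -> class 1); the
    majority class is randomly down-sampled to the minority size, the 0.632+
    AUC computed on the balanced set, and the mean over ``n_undersample``
    draws reported.  Balanced labels make the under-sampling a no-op and a
    single evaluation is returned.
    """
    cfg = cfg or BootstrapConfig()
    rates = np.asarray(rates, dtype=float)
    feats = candidate_features if candidate_features is not None else list(feature_matrix.feature_names)
    rng = np.random.default_rng(seed)
    out: dict[float, float] = {}
    for thr in thresholds:
        y = (rates > thr).astype(int)
        n1, n0 = int(y.sum()), int((y == 0).sum())
        if n1 == 0 or n0 == 0:
            warnings.warn(f"threshold {thr}: one class empty, skipped")
            continue
        minority = 1 if n1 < n0 else 0
        n_min = min(n1, n0)
        if n1 == n0:
            res = auc632plus(None, y, spec, features=feats, cfg=cfg,
                             feature_matrix=feature_matrix)
            out[thr] = res.auc
            continue
        vals = []
        min_idx = np.where(y == minority)[0]
        maj_idx = np.where(y != minority)[0]
        for _ in range(n_undersample):
            keep_maj = rng.choice(maj_idx, size=n_min, replace=False)
            idx = np.sort(np.concatenate([min_idx, keep_maj]))
            sub = FeatureMatrix(
                feature_matrix.values[idx], list(feature_matrix.feature_names),
                [feature_matrix.sample_ids[i] for i in idx],
                normalized=feature_matrix.normalized,
            )
            res = auc632plus(None, y[idx], spec, features=feats, cfg=cfg,
                             feature_matrix=sub)
            vals.append(res.auc)
        out[thr] = float(np.mean(vals))
    return out


def volume_correlation_check(feature_matrix: FeatureMatrix, volumes: np.ndarray,
                             features: list[str] | None = None) -> dict[str, float]:
    """Spearman rho of each (selected) feature against tumor volume."""
    volumes = np.asarray(volumes, dtype=float)
    if volumes.size != feature_matrix.n_samples:
        raise ValueError("volumes must align with samples")
    feats = features if features is not None else list(feature_matrix.feature_names)
    out = {}
    for name in feats:
        col = feature_matrix.column(name)
        if np.all(col == col[0]):
            out[name] = float("nan")
            continue
        rho = stats.spearmanr(col, volumes).statistic
        out[name] = float(rho)
    return out
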