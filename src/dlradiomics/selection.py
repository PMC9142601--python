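"""Two-step feature selection: robustness and redundancy filters, then rankers.

Step 1 removes fragile and redundant features:

* robustness — each feature's values over alternative segmentations of the
  same subjects are scored with the two-way mixed-effects, absolute-agreement,
  single-measurement intraclass correlation (ICC "Case 3A" in the
  McGraw–Wong taxonomy); features with ICC strictly above the threshold
  (default 0.7) are kept;
* redundancy — pairs with |Spearman rho| strictly above the threshold
  (default 0.8) are resolved by dropping, from the most-correlated offending
  pair, the member with the higher mean |rho| against all other retained
  features, iterating until no offending pair remains.

Step 2 ranks the surviving features with five filter methods — chi-square
score (CHSQ), Wilcoxon rank-sum (WLCX), neighborhood component analysis
(NCA), ReliefF, and infinite feature selection (infFS) — and keeps the top-k
(default 10) per method.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .features import FeatureMatrix

RANKERS = ("CHSQ", "WLCX", "NCA", "ReliefF", "infFS")


@dataclass(frozen=True)
class SelectionConfig:
    icc_threshold: float = 0.7
    corr_threshold: float = 0.8
    top_k: int = 10
    ranker: str = "WLCX"
    chsq_bins: int = 10
    relieff_k: int = 10
    nca_ridge: float | None = None  # default 1/n
    inffs_alpha: float = 0.5
    inffs_r_scale: float = 0.9  # r = scale / spectral_radius(A)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.icc_threshold < 1) or not (0 < self.corr_threshold < 1):
            raise ValueError("thresholds must lie in (0, 1)")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.ranker not in RANKERS:
            raise ValueError(f"unknown ranker {self.ranker!r}; expected one of {RANKERS}")


@dataclass
class RankerResult:
    method: str
    feature_names: list[str]  # descending score, ties by original feature index
    scores: np.ndarray

    def top(self, k: int) -> list[str]:
        return self.feature_names[:k]


@dataclass
class MultiSegFeatureSet:
    """Per-feature (subjects x raters) value tables from repeated segmentations."""

    tables: dict[str, np.ndarray] = field(default_factory=dict)

    def add(self, name: str, matrix: np.ndarray) -> None:
        m = np.asarray(matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
            raise ValueError("need >= 2 subjects and >= 2 raters")
        if not np.all(np.isfinite(m)):
            raise ValueError("missing cells not allowed")
        self.tables[name] = m

    @classmethod
    def from_stack(cls, values: np.ndarray, feature_names: list[str]) -> "MultiSegFeatureSet":
        """From a (subjects, raters, features) stack."""
        ms = cls()
        values = np.asarray(values, dtype=float)
        for j, name in enumerate(feature_names):
            ms.add(name, values[:, :, j])
        return ms


def icc_case3a(matrix: np.ndarray) -> float:
    """Two-way mixed, absolute-agreement, single-measurement ICC.

    From the two-way ANOVA mean squares (rows = subjects, columns = raters):
    ``(MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))``.  Returns NaN with
    a warning when the table has no variance at all.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need >= 2 subjects and >= 2 raters")
    n, k = m.shape
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((m - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if ss_total == 0 or denom == 0:
        warnings.warn("ICC undefined: zero total variance")
        return float("nan")
    return float((msr - mse) / denom)


def filter_robust(ms: MultiSegFeatureSet, cfg: SelectionConfig | None = None) -> list[str]:
    """Names of features whose ICC is strictly above the threshold."""
    cfg = cfg or SelectionConfig()
    kept = []
    for name, table in ms.tables.items():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            icc = icc_case3a(table)
        if np.isfinite(icc) and icc > cfg.icc_threshold:
            kept.append(name)
    return kept


def _spearman_matrix(x: np.ndarray) -> np.ndarray:
    rho = stats.spearmanr(x).statistic
    if np.isscalar(rho):  # two-feature case
        rho = np.array([[1.0, rho], [rho, 1.0]])
    rho = np.asarray(rho, dtype=float)
    np.fill_diagonal(rho, 1.0)
    return np.nan_to_num(rho, nan=0.0)  # constant features: treat as uncorrelated


def prune_collinear(fm: FeatureMatrix, cfg: SelectionConfig | None = None) -> list[str]:
    """Drop redundant features until no retained pair has |Spearman rho| > threshold.

    At each step the most-correlated offending pair is examined; the member
    with the higher mean |rho| against all other retained features is dropped
    (tie -> higher column index), and correlations are re-examined on the
    reduced set.
    """
    cfg = cfg or SelectionConfig()
    names = list(fm.feature_names)
    if len(names) < 2:
        return names
    rho = np.abs(_spearman_matrix(fm.values))
    alive = np.ones(len(names), dtype=bool)
    while True:
        sub = np.where(alive)[0]
        if sub.size < 2:
            break
        r = rho[np.ix_(sub, sub)].copy()
        np.fill_diagonal(r, 0.0)
        if r.max() <= cfg.corr_threshold:
            break
        a_loc, b_loc = np.unravel_index(np.argmax(r), r.shape)  # first maximizer
        a, b = sub[a_loc], sub[b_loc]

        def mean_abs(i: int) -> float:
            others = sub[sub != i]
            return float(rho[i, others].mean()) if others.size else 0.0

        ma, mb = mean_abs(a), mean_abs(b)
        if np.isclose(ma, mb):
            drop = max(a, b)  # tie -> higher column index
        else:
            drop = a if ma > mb else b
        alive[drop] = False
    return [names[i] for i in np.where(alive)[0]]


# ---------------------------------------------------------------------------
# rankers

def _order_by_score(names: list[str], scores: np.ndarray) -> tuple[list[str], np.ndarray]:
    # descending score; ties broken by ascending original feature index
    idx = np.lexsort((np.arange(len(names)), -scores))
    return [names[i] for i in idx], scores[idx]


def _chsq_scores(x: np.ndarray, y: np.ndarray, bins: int) -> np.ndarray:
    scores = np.zeros(x.shape[1])
    for j in range(x.shape[1]):
        col = x[:, j]
        qs = np.quantile(col, np.linspace(0, 1, bins + 1))
        edges = np.unique(qs)
        if edges.size < 2:
            scores[j] = 0.0
            continue
        binned = np.clip(np.searchsorted(edges, col, side="right") - 1, 0, edges.size - 2)
        table = np.zeros((edges.size - 1, 2))
        np.add.at(table, (binned, y.astype(int)), 1.0)
        table = table[table.sum(axis=1) > 0]
        if table.shape[0] < 2:
            scores[j] = 0.0
            continue
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        scores[j] = -np.log10(max(p, 1e-300))
    return scores


def _wlcx_scores(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    scores = np.zeros(x.shape[1])
    for j in range(x.shape[1]):
        stat, p = stats.ranksums(x[y == 1, j], x[y == 0, j])
        scores[j] = -np.log10(max(p, 1e-300))
    return scores


def _relieff_scores(x: np.ndarray, y: np.ndarray, k: int) -> np.ndarray:
    """ReliefF expected-margin weights: k nearest hits/misses, all instances,
    Manhattan distance, miss contributions weighted by class priors."""
    n, p = x.shape
    rng_span = x.max(axis=0) - x.min(axis=0)
    rng_span[rng_span == 0] = 1.0
    classes, counts = np.unique(y, return_counts=True)
    priors = dict(zip(classes, counts / n))
    dist = np.abs(x[:, None, :] - x[None, :, :]).sum(axis=2)
    np.fill_diagonal(dist, np.inf)
    w = np.zeros(p)
    for i in range(n):
        diffs_i = np.abs(x[i] - x) / rng_span
        same = np.where(y == y[i])[0]
        same = same[same != i]
        kh = min(k, same.size)
        if kh > 0:
            hits = same[np.argsort(dist[i, same], kind="stable")[:kh]]
            w -= diffs_i[hits].mean(axis=0)
        for c in classes:
            if c == y[i]:
                continue
            other = np.where(y == c)[0]
            km = min(k, other.size)
            if km == 0:
                continue
            misses = other[np.argsort(dist[i, other], kind="stable")[:km]]
            w += priors[c] / (1.0 - priors[y[i]]) * diffs_i[misses].mean(axis=0)
    return w / n


def _nca_scores(x: np.ndarray, y: np.ndarray, ridge: float | None, seed: int) -> np.ndarray:
    """Diagonal NCA: weights w maximize the expected leave-one-out
    stochastic-neighbor accuracy with squared-weight distance
    d(i,j) = sum_r w_r^2 |x_ir - x_jr|, minus a ridge penalty."""
    n, p = x.shape
    lam = 1.0 / n if ridge is None else ridge
    same = (y[:, None] == y[None, :]).astype(float)
    np.fill_diagonal(same, 0.0)
    absdiff = np.abs(x[:, None, :] - x[None, :, :])  # (n, n, p)

    def neg_obj_grad(w):
        w2 = w**2
        d = absdiff @ w2
        np.fill_diagonal(d, np.inf)
        logits = -d
        logits -= logits.max(axis=1, keepdims=True)
        ex = np.exp(logits)
        np.fill_diagonal(ex, 0.0)
        denom = ex.sum(axis=1, keepdims=True)
        denom[denom == 0] = 1.0
        prob = ex / denom  # p_ij
        pi = (prob * same).sum(axis=1)
        obj = pi.sum() - lam * (w2).sum()
        # d obj / d w_r = sum_i [ p_i * E_j(absdiff) - E_{j in class}(absdiff) ] * 2 w_r
        e_all = np.einsum("ij,ijr->ir", prob, absdiff)
        e_same = np.einsum("ij,ijr->ir", prob * same, absdiff)
        grad = 2.0 * w * ((pi[:, None] * e_all - e_same).sum(axis=0)) - 2.0 * lam * w
        return -obj, -grad

    w0 = np.ones(p)
    res = optimize.minimize(neg_obj_grad, w0, jac=True, method="L-BFGS-B",
                            options={"maxiter": 200})
    return res.x**2


def inffs_adjacency(x: np.ndarray, y: np.ndarray, alpha: float) -> np.ndarray:
    """infFS adjacency: a_ij = alpha*max(s_i, s_j) + (1-alpha)*(1-|rho_S(i,j)|).

    ``s_i`` is the supervised per-feature relevance prior — the Fisher-type
    standardized class separation |mu_1 - mu_0| / sqrt(sd_1^2 + sd_0^2),
    rescaled to [0, 1] — as in the supervised variant of the algorithm.  (A
    class-blind spread prior is useless on z-scored cohorts, where every
    feature has unit total variance.)  The second term rewards mutual
    non-redundancy via Spearman correlation.
    """
    mu1, mu0 = x[y == 1].mean(axis=0), x[y == 0].mean(axis=0)
    sd1, sd0 = x[y == 1].std(axis=0), x[y == 0].std(axis=0)
    denom = np.sqrt(sd1**2 + sd0**2)
    denom[denom == 0] = 1.0
    s = np.abs(mu1 - mu0) / denom
    if s.max() > 0:
        s = s / s.max()
    smax = np.maximum(s[:, None], s[None, :])
    rho = np.abs(_spearman_matrix(x))
    return alpha * smax + (1.0 - alpha) * (1.0 - rho)


def _inffs_scores(x: np.ndarray, y: np.ndarray, alpha: float, r_scale: float) -> np.ndarray:
    a = inffs_adjacency(x, y, alpha)
    spectral = np.max(np.abs(np.linalg.eigvals(a)))
    r = r_scale / spectral if spectral > 0 else r_scale
    s = np.linalg.inv(np.eye(a.shape[0]) - r * a) - np.eye(a.shape[0])
    return s.sum(axis=1)


def rank_features(fm: FeatureMatrix, labels: np.ndarray,
                  cfg: SelectionConfig | None = None) -> RankerResult:
    """Rank features with the configured filter method; top-k via ``RankerResult.top``."""
    cfg = cfg or SelectionConfig()
    y = np.asarray(labels).astype(int)
    if np.unique(y).size < 2:
        raise ValueError("labels must contain both classes")
    x = fm.values
    if cfg.ranker == "CHSQ":
        scores = _chsq_scores(x, y, cfg.chsq_bins)
    elif cfg.ranker == "WLCX":
        scores = _wlcx_scores(x, y)
    elif cfg.ranker == "NCA":
        scores = _nca_scores(x, y, cfg.nca_ridge, cfg.seed)
    elif cfg.ranker == "ReliefF":
        scores = _relieff_scores(x, y, cfg.relieff_k)
    else:  # infFS
        scores = _inffs_scores(x, y, cfg.inffs_alpha, cfg.inffs_r_scale)
    names, ordered = _order_by_score(list(fm.feature_names), scores)
    return RankerResult(method=cfg.ranker, feature_names=names, scores=ordered)


def top_k_per_ranker(fm: FeatureMatrix, labels: np.ndarray,
                     cfg: SelectionConfig | None = None) -> dict[str, list[str]]:
    """Top-k feature lists for all five rankers (keys = ranker names)."""
    cfg = cfg or SelectionConfig()
    out = {}
    for ranker in RANKERS:
        rcfg = SelectionConfig(**{**cfg.__dict__, "ranker": ranker})
        out[ranker] = rank_features(fm, labels, rcfg).top(cfg.top_k)
    return out
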