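"""Synthetic fixtures with known ground truth.

Three generators cover every input the pipeline consumes:

* :func:`make_phantom` — a textured ellipsoidal tumor in an HU-valued volume
  (smoothed Gaussian texture inside the mask, constant background), standing
  in for patient planning CTs;
* :func:`perturb_segmentations` — families of boundary-perturbed masks,
  standing in for public multi-segmentation robustness data;
* :func:`make_feature_cohort` — feature cohorts with planted informative,
  redundant and noise features plus binary labels, standing in for deep
  feature matrices.

Every generator is a pure function of its spec (seed included).  These
fixtures exercise the pipeline's branches — robust vs fragile, redundant vs
independent, informative vs noise — but make no claim of anatomical realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .features import FeatureMatrix
from .imaging import CTVolume, SegMask


@dataclass(frozen=True)
class PhantomSpec:
    shape: tuple[int, int, int] = (64, 64, 48)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    semi_axes_mm: tuple[float, float, float] = (12.0, 10.0, 8.0)
    center_mm: tuple[float, float, float] | None = None  # None = volume center
    tumor_mean_hu: float = 60.0
    tumor_sd_hu: float = 40.0
    smoothing_mm: float = 1.5
    background_hu: float = -1000.0
    seed: int = 0


@dataclass(frozen=True)
class CohortSpec:
    n_samples: int = 200
    n_features: int = 10
    n_informative: int = 1
    effect_size: float = 1.5  # standardized between-class mean shift
    n_redundant: int = 0
    redundant_rho: float = 0.95  # target Spearman correlation with the parent
    class_balance: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative + self.n_redundant > self.n_features:
            raise ValueError("n_informative + n_redundant must be <= n_features")
        if self.effect_size < 0:
            raise ValueError("effect size must be >= 0")
        if not (0 < self.class_balance < 1):
            raise ValueError("class_balance must be in (0, 1)")


def make_phantom(spec: PhantomSpec | None = None) -> tuple[CTVolume, SegMask]:
    """Ellipsoidal tumor with smoothed Gaussian HU texture on constant background."""
    spec = spec or PhantomSpec()
    shape = tuple(int(s) for s in spec.shape)
    sp = np.asarray(spec.spacing, dtype=float)
    center = (np.asarray(spec.center_mm, dtype=float)
              if spec.center_mm is not None
              else (np.asarray(shape) * sp) / 2.0)
    semi = np.asarray(spec.semi_axes_mm, dtype=float)
    if np.any(center - semi < 0) or np.any(center + semi > np.asarray(shape) * sp):
        raise ValueError("tumor does not fit inside the volume")
    # voxel centers in mm
    grids = np.meshgrid(*[(np.arange(n) + 0.5) * s for n, s in zip(shape, sp)], indexing="ij")
    d2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi))
    mask = (d2 <= 1.0).astype(np.uint8)
    rng = np.random.default_rng(spec.seed)
    noise = rng.standard_normal(shape)
    sigma_vox = spec.smoothing_mm / sp
    smooth = ndimage.gaussian_filter(noise, sigma=sigma_vox)
    sd = smooth.std()
    texture = spec.tumor_mean_hu + spec.tumor_sd_hu * (smooth / sd if sd > 0 else smooth)
    voxels = np.where(mask > 0, texture, spec.background_hu)
    return CTVolume(voxels, tuple(sp)), SegMask(mask)


def perturb_segmentations(
    mask: SegMask, n_raters: int = 9, magnitude: float = 1.0, seed: int = 0
) -> list[SegMask]:
    """Rater-like mask variants via smoothed boundary noise.

    The signed distance-like field (inside-positive) is perturbed with
    smoothed Gaussian surface noise scaled by ``magnitude`` (in voxels) and
    re-thresholded, so overlap with the original decreases as the magnitude
    grows.  ``magnitude = 0`` returns identical copies.
    """
    if mask.n_foreground == 0:
        raise ValueError("mask is empty")
    base = mask.voxels.astype(bool)
    if magnitude == 0:
        return [SegMask(mask.voxels.copy()) for _ in range(n_raters)]
    inside = ndimage.distance_transform_edt(base)
    outside = ndimage.distance_transform_edt(~base)
    signed = inside - outside
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_raters):
        noise = ndimage.gaussian_filter(rng.standard_normal(base.shape), sigma=2.0)
        noise = noise / noise.std()
        perturbed = (signed + magnitude * noise) > 0
        if not perturbed.any():
            raise ValueError("perturbation erased the mask; reduce magnitude")
        out.append(SegMask(perturbed.astype(np.uint8)))
    return out


def _calibrate_noise_for_spearman(parent: np.ndarray, rho_target: float,
                                  rng: np.random.Generator) -> np.ndarray:
    """Parent + scaled noise whose Spearman correlation hits the target.

    No closed form survives the rank transform, so the noise scale is found
    by bisection on the empirical Spearman correlation.
    """
    from scipy import stats

    if not (0 < rho_target < 1):
        raise ValueError("target Spearman correlation must be in (0, 1)")
    noise = rng.standard_normal(parent.size)
    lo, hi = 0.0, 50.0
    if stats.spearmanr(parent, parent + hi * noise).statistic > rho_target:
        raise ValueError("cannot reach target correlation (too low)")
    for _ in range(60):
        mid = (lo + hi) / 2.0
        rho = stats.spearmanr(parent, parent + mid * noise).statistic
        if rho > rho_target:
            lo = mid
        else:
            hi = mid
    return parent + ((lo + hi) / 2.0) * noise


def make_feature_cohort(spec: CohortSpec | None = None) -> tuple[FeatureMatrix, np.ndarray, dict]:
    """Cohort with planted informative / redundant / noise features.

    Informative features are unit-variance Gaussians whose class means differ
    by the standardized shift delta; redundant features are noisy copies of
    informative ones calibrated to the target Spearman correlation; the rest
    is independent noise.  Returns (features, labels, ground_truth) where
    ground_truth lists each feature's role.
    """
    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_samples, spec.n_features
    n_pos = int(round(n * spec.class_balance))
    y = np.zeros(n, dtype=int)
    y[:n_pos] = 1
    perm = rng.permutation(n)
    y = y[perm]

    x = rng.standard_normal((n, p))
    roles = {}
    informative = [f"feat_{j:03d}" for j in range(spec.n_informative)]
    for j in range(spec.n_informative):
        x[:, j] += spec.effect_size * y  # class-1 mean shifted by delta
        roles[f"feat_{j:03d}"] = "informative"
    for j in range(spec.n_informative, spec.n_informative + spec.n_redundant):
        parent = (j - spec.n_informative) % max(spec.n_informative, 1)
        x[:, j] = _calibrate_noise_for_spearman(x[:, parent], spec.redundant_rho, rng)
        roles[f"feat_{j:03d}"] = f"redundant_of_feat_{parent:03d}"
    for j in range(spec.n_informative + spec.n_redundant, p):
        roles[f"feat_{j:03d}"] = "noise"

    names = [f"feat_{j:03d}" for j in range(p)]
    fm = FeatureMatrix(x, names, [f"patient_{i:04d}" for i in range(n)],
                       provenance={"backbone": "synthetic"})
    truth = {"roles": roles, "informative": informative, "effect_size": spec.effect_size}
    return fm, y, truth
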