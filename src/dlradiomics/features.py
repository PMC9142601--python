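"""Deep-feature extraction behind a pluggable frozen-backbone contract.

A backbone is any callable mapping a (H, W, 3) image in [0, 1] to a fixed-length
feature vector.  Pretrained CNN adapters register themselves under their name;
weights are never bundled with the package.  The reference backend is a
deterministic stub: a seeded random linear projection of the flattened image
followed by tanh, which gives the pipeline a reproducible 1000-dimensional
feature map without any pretrained weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class ConfigurationError(ValueError):
    """Unknown backbone or otherwise invalid extractor configuration."""


#: Backbones tapped at the last fully connected layer, plus the three that
#: lack one and are tapped at the layer before the last softmax.
KNOWN_BACKBONES = (
    "SqueezeNet", "GoogleNet", "Inceptionv3", "DenseNet201", "MobileNetv2",
    "ResNet18", "ResNet50", "ResNet101", "Xception", "InceptionResNetv2",
    "ShuffleNet", "NASNetMobile", "NASNetLarge", "DarkNet19", "DarkNet53",
    "AlexNet",
)
PRE_SOFTMAX_BACKBONES = ("SqueezeNet", "DarkNet19", "DarkNet53")


@dataclass(frozen=True)
class ExtractorSpec:
    backbone: str = "stub"
    layer: str = "last fully connected"
    output_dim: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.output_dim < 1:
            raise ConfigurationError("output_dim must be >= 1")
        if self.backbone != "stub" and self.backbone not in KNOWN_BACKBONES:
            raise ConfigurationError(
                f"unknown backbone {self.backbone!r}; expected 'stub' or one of {KNOWN_BACKBONES}"
            )


@dataclass
class FeatureMatrix:
    """Samples x named features, with sample identifiers and a normalization flag."""

    values: np.ndarray
    feature_names: list[str]
    sample_ids: list[str]
    normalized: bool = False
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2D (samples x features)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")
        if len(self.feature_names) != self.values.shape[1]:
            raise ValueError("feature_names length mismatch")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")
        if len(self.sample_ids) != self.values.shape[0]:
            raise ValueError("sample_ids length mismatch")
        self.feature_names = [str(n) for n in self.feature_names]
        self.sample_ids = [str(s) for s in self.sample_ids]

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.feature_names.index(name)]

    def subset(self, names: list[str]) -> "FeatureMatrix":
        cols = [self.feature_names.index(n) for n in names]
        return FeatureMatrix(
            self.values[:, cols], list(names), list(self.sample_ids),
            normalized=self.normalized, provenance=dict(self.provenance),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_names)

    def to_csv(self, path) -> None:
        df = self.to_frame()
        df.index.name = "sample_id"
        df.to_csv(path)  # default shortest-repr floats round-trip exactly

    @classmethod
    def from_csv(cls, path, normalized: bool = False) -> "FeatureMatrix":
        df = pd.read_csv(path, index_col=0, float_precision="round_trip")
        return cls(
            df.to_numpy(dtype=float),
            [str(c) for c in df.columns],
            [str(i) for i in df.index],
            normalized=normalized,
        )


def stub_extractor(image: np.ndarray, seed: int = 0, dim: int = 1000) -> np.ndarray:
    """Deterministic stand-in feature map: tanh of a seeded random projection.

    The projection matrix and bias depend only on ``seed`` and the flattened
    image length, so the same seed gives the same map across runs and
    platforms.  The map is not scale-invariant and is injective with high
    probability for images of practical size.
    """
    x = np.asarray(image, dtype=float)
    if x.ndim == 3:
        x = x[:, :, 0]
    flat = x.ravel()
    rng = np.random.default_rng(seed)
    w = rng.standard_normal((dim, flat.size)) / np.sqrt(flat.size)
    b = rng.standard_normal(dim) * 0.1
    return np.tanh(w @ flat + b)


class _StubBackbone:
    """Caches the projection so a batch of crops shares one map."""

    input_px = 64

    def __init__(self, spec: ExtractorSpec):
        self.spec = spec
        self._w = None
        self._b = None

    def __call__(self, image: np.ndarray) -> np.ndarray:
        x = np.asarray(image, dtype=float)
        if x.ndim == 3:
            x = x[:, :, 0]
        flat = x.ravel()
        if self._w is None or self._w.shape[1] != flat.size:
            rng = np.random.default_rng(self.spec.seed)
            self._w = rng.standard_normal((self.spec.output_dim, flat.size)) / np.sqrt(flat.size)
            self._b = rng.standard_normal(self.spec.output_dim) * 0.1
        return np.tanh(self._w @ flat + self._b)


_BACKBONE_REGISTRY: dict[str, type] = {"stub": _StubBackbone}


def register_backbone(name: str, factory) -> None:
    """Register a backbone adapter (e.g. a wrapper around a pretrained CNN)."""
    _BACKBONE_REGISTRY[name] = factory


def extract_features(crops: list, spec: ExtractorSpec | None = None) -> FeatureMatrix:
    """One feature row per crop from the configured frozen backbone."""
    spec = spec or ExtractorSpec()
    if spec.backbone not in _BACKBONE_REGISTRY:
        raise ConfigurationError(
            f"backbone {spec.backbone!r} has no registered adapter; "
            f"available: {sorted(_BACKBONE_REGISTRY)}"
        )
    backbone = _BACKBONE_REGISTRY[spec.backbone](spec)
    rows, ids = [], []
    for i, crop in enumerate(crops):
        pixels = crop.pixels if hasattr(crop, "pixels") else np.asarray(crop)
        vec = np.asarray(backbone(pixels), dtype=float)
        if vec.shape != (spec.output_dim,):
            raise ConfigurationError(
                f"backbone returned shape {vec.shape}, expected ({spec.output_dim},)"
            )
        rows.append(vec)
        ids.append(f"sample_{i}")
    names = [f"{spec.backbone}_f{j:04d}" for j in range(spec.output_dim)]
    return FeatureMatrix(
        np.vstack(rows), names, ids,
        provenance={"backbone": spec.backbone, "layer": spec.layer, "seed": spec.seed},
    )


def zscore_normalize(fm: FeatureMatrix) -> FeatureMatrix:
    """Per-feature z-score over the cohort (sample SD, n-1 denominator).

    Constant columns map to all zeros with a warning rather than failing, so
    degenerate features cannot crash the pipeline.
    """
    if fm.n_samples < 2:
        raise ValueError("z-score requires at least 2 samples")
    mu = fm.values.mean(axis=0)
    sd = fm.values.std(axis=0, ddof=1)
    const = sd == 0
    if const.any():
        warnings.warn(f"{int(const.sum())} constant feature(s) mapped to zeros in z-score")
    sd_safe = np.where(const, 1.0, sd)
    vals = (fm.values - mu) / sd_safe
    vals[:, const] = 0.0
    return FeatureMatrix(
        vals, list(fm.feature_names), list(fm.sample_ids),
        normalized=True, provenance={**fm.provenance, "zscore": "cohort, ddof=1"},
    )
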