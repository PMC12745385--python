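"""Handcrafted + deep feature extraction and fusion.

Each standardized 224 x 224 slice yields two blocks:

* a 512-d handcrafted block: scale-invariant keypoint descriptors (SIFT,
  128-d each) pooled by four permutation-invariant moments
  (mean, sd, max, min), 4 x 128 = 512;
* a 4096-d deep block from a convolutional backbone — either the penultimate
  fully-connected activation of a pretrained VGG16 (optional plug-in,
  requires torchvision) or a download-free stub: a seeded fixed random
  linear projection of the (average-pooled) flattened 3-channel image
  followed by half-wave rectification.

The fused representation concatenates them, handcrafted first:
``F_fused = [F_sift | F_deep]``, 512 + 4096 = 4608 dimensions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.feature import SIFT as _SkSIFT

from .phantom import Cohort
from .preprocess import RoiConfig, quadrant_roi, standardize_slice

__all__ = [
    "SIFT_DIM",
    "DEEP_DIM",
    "FUSED_DIM",
    "BLOCK_SPANS",
    "DescriptorSet",
    "FeatureBlock",
    "FusedVector",
    "BackboneSpec",
    "extract_descriptors",
    "aggregate_sift",
    "to_three_channel",
    "deep_embed",
    "stub_projection",
    "fuse",
    "featurize_case",
    "featurize_cohort",
]

SIFT_DIM = 512
DEEP_DIM = 4096
FUSED_DIM = SIFT_DIM + DEEP_DIM
assert FUSED_DIM == 4608

#: half-open column spans of the two blocks inside a fused vector
BLOCK_SPANS = {"sift": (0, SIFT_DIM), "deep": (SIFT_DIM, FUSED_DIM)}


@dataclass
class DescriptorSet:
    """k local keypoint descriptors (k x 128, L2-normalized rows) with
    (row, col, scale) keypoint locations; k may be zero."""

    descriptors: np.ndarray
    keypoints: np.ndarray

    def __post_init__(self) -> None:
        self.descriptors = np.asarray(self.descriptors, dtype=float).reshape(-1, 128)
        self.keypoints = np.asarray(self.keypoints, dtype=float).reshape(-1, 3)
        if len(self.descriptors) != len(self.keypoints):
            raise ValueError("descriptor/keypoint count mismatch")

    def __len__(self) -> int:
        return len(self.descriptors)


@dataclass
class FeatureBlock:
    kind: str           # "sift" | "deep"
    values: np.ndarray

    _LEN = {"sift": SIFT_DIM, "deep": DEEP_DIM}

    def __post_init__(self) -> None:
        if self.kind not in self._LEN:
            raise ValueError(f"unknown block kind {self.kind!r}")
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size != self._LEN[self.kind]:
            raise ValueError(
                f"{self.kind} block must have length {self._LEN[self.kind]}, "
                f"got {self.values.size}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite feature values")


@dataclass
class FusedVector:
    values: np.ndarray
    block_spans: dict = field(default_factory=lambda: dict(BLOCK_SPANS))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size != FUSED_DIM:
            raise ValueError(f"fused vector must have length {FUSED_DIM}")

    def block(self, kind: str) -> np.ndarray:
        a, b = self.block_spans[kind]
        return self.values[a:b]


@dataclass(frozen=True)
class BackboneSpec:
    """Deep-embedding backbone choice.

    ``stub`` needs no downloads and is fully seeded; ``vgg16-pretrained``
    uses torchvision's VGG16 with the final classification layer removed
    (the 4096-d penultimate fully-connected activation).
    """

    name: str = "stub"
    seed: int = 0
    output_dim: int = DEEP_DIM

    def __post_init__(self) -> None:
        if self.name not in ("stub", "vgg16-pretrained"):
            raise ValueError(f"unknown backbone {self.name!r}")
        if self.output_dim != DEEP_DIM:
            raise ValueError(f"output_dim must be {DEEP_DIM}")


# ---------------------------------------------------------------------------
# handcrafted block
# ---------------------------------------------------------------------------

def extract_descriptors(img: np.ndarray) -> DescriptorSet:
    """Scale-invariant keypoints + 128-d descriptors on the 8-bit
    quantization of a standardized slice; rows L2-normalized.  Images with
    no detectable extrema (e.g. constant) yield an empty set."""
    a = np.asarray(img, dtype=float)
    if a.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    u8 = np.clip(a * 255.0, 0, 255).astype(np.uint8)
    det = _SkSIFT()
    try:
        det.detect_and_extract(u8)
    except RuntimeError:  # no features found
        return DescriptorSet(np.empty((0, 128)), np.empty((0, 3)))
    desc = det.descriptors.astype(float)
    norms = np.linalg.norm(desc, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    desc = desc / norms
    kps = np.column_stack([det.keypoints.astype(float), det.scales])
    return DescriptorSet(desc, kps)


def aggregate_sift(ds: DescriptorSet) -> FeatureBlock:
    """Pool a variable-size descriptor set into a fixed 512-d block:
    concat(mean, sd, max, min) over descriptor rows (sd with ddof=0);
    an empty set pools to the zero vector."""
    if len(ds) == 0:
        return FeatureBlock("sift", np.zeros(SIFT_DIM))
    d = ds.descriptors
    pooled = np.concatenate([d.mean(axis=0), d.std(axis=0, ddof=0),
                             d.max(axis=0), d.min(axis=0)])
    return FeatureBlock("sift", pooled)


# ---------------------------------------------------------------------------
# deep block
# ---------------------------------------------------------------------------

def to_three_channel(img: np.ndarray) -> np.ndarray:
    """Replicate a single-channel image to 3 identical channels (3, H, W)."""
    a = np.asarray(img, dtype=float)
    if a.ndim != 2:
        raise ValueError("expected a single-channel 2-D image")
    return np.broadcast_to(a, (3,) + a.shape).copy()


_POOL_TARGET = 28  # stub average-pools each channel to at most 28 x 28

_stub_cache: dict = {}


def _stub_weights(seed: int, out_dim: int, in_dim: int) -> np.ndarray:
    key = (seed, out_dim, in_dim)
    if key not in _stub_cache:
        rng = np.random.default_rng(seed)
        W = rng.standard_normal((out_dim, in_dim)) / np.sqrt(in_dim)
        # row-center: each unit ignores the image's DC level, so the shared
        # background of standardized slices cannot pin units at zero
        W -= W.mean(axis=1, keepdims=True)
        _stub_cache[key] = W
    return _stub_cache[key]


def _avg_pool(ch: np.ndarray, factor: int) -> np.ndarray:
    if factor <= 1:
        return ch
    h, w = ch.shape
    h2, w2 = h - h % factor, w - w % factor
    return ch[:h2, :w2].reshape(h2 // factor, factor, w2 // factor, factor).mean(axis=(1, 3))


def stub_projection(img3: np.ndarray, seed: int, output_dim: int) -> np.ndarray:
    """Seeded fixed random linear map of the flattened (pooled) image,
    half-wave rectified: y = max(W x, 0) with W ~ N(0, 1/in_dim) from
    ``default_rng(seed)``.  Pure function of (image, seed, output_dim)."""
    x = np.asarray(img3, dtype=float)
    factor = max(1, int(np.ceil(max(x.shape[-2:]) / _POOL_TARGET)))
    pooled = np.stack([_avg_pool(c, factor) for c in x])
    flat = pooled.ravel()
    W = _stub_weights(seed, output_dim, flat.size)
    return np.maximum(W @ flat, 0.0)


def deep_embed(img3: np.ndarray, spec: BackboneSpec = BackboneSpec()) -> FeatureBlock:
    """Map a (3, 224, 224) image in [0, 1] to the 4096-d deep block.

    Deterministic: the same spec and image always give identical output.
    """
    a = np.asarray(img3, dtype=float)
    if a.ndim != 3 or a.shape[0] != 3:
        raise ValueError(f"expected a (3, H, W) image, got shape {a.shape}")
    if spec.name == "stub":
        return FeatureBlock("deep", stub_projection(a, spec.seed, spec.output_dim))
    return FeatureBlock("deep", _vgg16_embed(a))


def _vgg16_embed(img3: np.ndarray) -> np.ndarray:
    try:
        import torch
        from torchvision.models import VGG16_Weights, vgg16
    except ImportError as exc:  # pragma: no cover - optional plug-in
        raise ImportError(
            "the vgg16-pretrained backbone requires the optional torch/"
            "torchvision dependency (pip install 'spinefuse[vgg16]')"
        ) from exc
    mean = np.array([0.485, 0.456, 0.406])[:, None, None]
    std = np.array([0.229, 0.224, 0.225])[:, None, None]
    x = torch.as_tensor((img3 - mean) / std, dtype=torch.float32)[None]
    model = vgg16(weights=VGG16_Weights.IMAGENET1K_V1).eval()
    trunk = torch.nn.Sequential(model.features, model.avgpool,
                                torch.nn.Flatten(1),
                                *list(model.classifier.children())[:-1])
    with torch.no_grad():
        return trunk(x).numpy().ravel()


# ---------------------------------------------------------------------------
# fusion
# ---------------------------------------------------------------------------

def fuse(sift: FeatureBlock, deep: FeatureBlock) -> FusedVector:
    """Concatenate handcrafted-then-deep into the 4608-d fused vector."""
    if sift.kind != "sift" or deep.kind != "deep":
        raise ValueError(f"expected (sift, deep) blocks, got "
                         f"({sift.kind!r}, {deep.kind!r})")
    return FusedVector(np.concatenate([sift.values, deep.values]))


def featurize_case(stack, modality: str, backbone: BackboneSpec = BackboneSpec(),
                   roi_cfg: RoiConfig = RoiConfig()) -> FusedVector:
    """ROI -> standardize -> (SIFT pooling || deep embedding) -> fuse for
    one case's configured modality channel.

    The ROI is detected on the first listed channel (channels are
    co-registered) and applied to the requested modality.
    """
    if modality not in stack.channels:
        raise ValueError(
            f"case {stack.case_id!r} has no modality {modality!r}; "
            f"available: {list(stack.channels)}")
    first = next(iter(stack.channels.values()))
    roi = quadrant_roi(first, roi_cfg)
    std = standardize_slice(stack.channels[modality], roi)
    sift_block = aggregate_sift(extract_descriptors(std))
    deep_block = deep_embed(to_three_channel(std), backbone)
    return fuse(sift_block, deep_block)


def featurize_cohort(cohort: Cohort, modality: str = "t2",
                     backbone: BackboneSpec = BackboneSpec(),
                     roi_cfg: RoiConfig = RoiConfig()):
    """Feature matrix (n x 4608) plus labels for a cohort, row order
    following cohort order."""
    rows, labels = [], []
    for case in cohort.cases:
        rows.append(featurize_case(case, modality, backbone, roi_cfg).values)
        labels.append(case.label)
    return np.vstack(rows), np.asarray(labels)
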