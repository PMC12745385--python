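"""Synthetic spinal-MRI phantom cohorts.

The real study population behind this pipeline — preoperative spinal MRI of
histologically confirmed intramedullary tumors (astrocytoma, ependymoma,
hemangioblastoma) — is private.  This module emulates its published summary
statistics: three tumor classes with class-conditional tumor / edema / cavity
sizes (mean ± sd on a cm^3 scale), co-registered T1 / T2 / contrast-enhanced
channels, an off-center bright spinal-canal stripe, scanner-like intensity
variation, and additive Gaussian noise.

Component sizes are drawn from log-normal distributions moment-matched to the
published (mean, sd) pairs: several cells have sd > mean (e.g. 2.3 ± 4.9),
which a truncated normal cannot honour while a log-normal reproduces both
moments exactly and guarantees positivity.  A drawn volume V (cm^3) is
rendered as the great-circle area of the equivalent sphere,
``A = pi * (3V / 4pi)^(2/3)`` cm^2, because the pipeline operates on single
axial slices.

Everything here is a pure function of its seed and parameters.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "ClassProfile",
    "SliceStack",
    "Cohort",
    "AugmentConfig",
    "FeatureFixture",
    "DEFAULT_PROFILES",
    "DEFAULT_CLASS_COUNTS",
    "strong_separation_profiles",
    "lognormal_params",
    "draw_volumes",
    "volume_to_area_cm2",
    "generate_phantom",
    "generate_cohort",
    "augment",
    "make_feature_fixture",
]

DEFAULT_MODALITIES = ("t1", "t2", "ce")

#: Relative contrast of the tumor/edema/cavity components per MRI sequence.
#: T1 shows lesions faintly, T2 accentuates fluid, contrast-enhanced (ce)
#: accentuates enhancing tumor.  Applied as a gain on the class's component
#: intensity offsets, never on the background, so zero offsets stay zero.
_MODALITY_GAIN = {"t1": 0.7, "t2": 1.25, "ce": 1.0}


@dataclass(frozen=True)
class ClassProfile:
    """Per-class generator parameters.

    Size parameters are on a cm^3 scale (mean, sd per component); intensity
    offsets are mean gray-level shifts in [-1, 1] added inside the component
    region; ``texture_scale`` is the spatial correlation length, in pixels,
    of the low-frequency texture field.
    """

    name: str
    tumor_vol_mean: float
    tumor_vol_sd: float
    edema_vol_mean: float
    edema_vol_sd: float
    cavity_vol_mean: float
    cavity_vol_sd: float
    intensity_offsets: dict = field(
        default_factory=lambda: {"tumor": 0.4, "edema": 0.18, "cavity": -0.15}
    )
    texture_scale: float = 8.0

    def __post_init__(self) -> None:
        for comp in ("tumor", "edema", "cavity"):
            if getattr(self, f"{comp}_vol_sd") < 0:
                raise ValueError(f"{comp}_vol_sd must be >= 0")
            if getattr(self, f"{comp}_vol_mean") <= 0:
                raise ValueError(f"{comp}_vol_mean must be > 0")
        if self.texture_scale <= 0:
            raise ValueError("texture_scale must be > 0")

    def component_params(self, comp: str) -> tuple[float, float]:
        return (
            getattr(self, f"{comp}_vol_mean"),
            getattr(self, f"{comp}_vol_sd"),
        )


#: Published class-conditional component-size statistics (cm^3, mean ± sd)
#: for the three intramedullary tumor types, with intensity offsets chosen to
#: caricature their typical MRI appearance (hemangioblastoma enhances most
#: avidly; astrocytoma is the least contrast-distinct).
DEFAULT_PROFILES: dict[str, ClassProfile] = {
    "astrocytoma": ClassProfile(
        name="astrocytoma",
        tumor_vol_mean=8.1, tumor_vol_sd=5.3,
        edema_vol_mean=6.8, edema_vol_sd=7.1,
        cavity_vol_mean=32.8, cavity_vol_sd=30.4,
        intensity_offsets={"tumor": 0.35, "edema": 0.15, "cavity": -0.10},
        texture_scale=8.0,
    ),
    "ependymoma": ClassProfile(
        name="ependymoma",
        tumor_vol_mean=7.6, tumor_vol_sd=3.1,
        edema_vol_mean=5.2, edema_vol_sd=4.6,
        cavity_vol_mean=20.3, cavity_vol_sd=19.7,
        intensity_offsets={"tumor": 0.45, "edema": 0.20, "cavity": -0.18},
        texture_scale=6.0,
    ),
    "hemangioblastoma": ClassProfile(
        name="hemangioblastoma",
        tumor_vol_mean=2.3, tumor_vol_sd=4.9,
        edema_vol_mean=16.5, edema_vol_sd=14.2,
        cavity_vol_mean=47.6, cavity_vol_sd=36.7,
        intensity_offsets={"tumor": 0.55, "edema": 0.25, "cavity": -0.25},
        texture_scale=10.0,
    ),
}

#: Class counts of the study cohort the phantom emulates (n = 316).
DEFAULT_CLASS_COUNTS = {"astrocytoma": 93, "ependymoma": 118, "hemangioblastoma": 105}


def strong_separation_profiles() -> dict:
    """Three synthetic classes with deliberately exaggerated geometric and
    contrast differences (bulky tumor / edema-dominant / syrinx-dominant).

    Unlike :data:`DEFAULT_PROFILES`, which emulate the published class
    statistics and overlap heavily, these are a recovery benchmark: a
    correct pipeline should classify them almost perfectly, so they anchor
    end-to-end sanity tests rather than realism.
    """
    return {
        "bulky-tumor": ClassProfile(
            name="bulky-tumor",
            tumor_vol_mean=22, tumor_vol_sd=2,
            edema_vol_mean=4, edema_vol_sd=0.5,
            cavity_vol_mean=4, cavity_vol_sd=0.5,
            intensity_offsets={"tumor": 0.6, "edema": 0.3, "cavity": -0.3},
            texture_scale=4.0),
        "edema-dominant": ClassProfile(
            name="edema-dominant",
            tumor_vol_mean=4, tumor_vol_sd=0.5,
            edema_vol_mean=28, edema_vol_sd=2,
            cavity_vol_mean=10, cavity_vol_sd=1,
            intensity_offsets={"tumor": 0.5, "edema": 0.2, "cavity": -0.2},
            texture_scale=12.0),
        "syrinx-dominant": ClassProfile(
            name="syrinx-dominant",
            tumor_vol_mean=10, tumor_vol_sd=1,
            edema_vol_mean=1, edema_vol_sd=0.2,
            cavity_vol_mean=60, cavity_vol_sd=5,
            intensity_offsets={"tumor": 0.4, "edema": 0.1, "cavity": -0.45},
            texture_scale=8.0),
    }


@dataclass
class SliceStack:
    """One case: co-registered per-modality 2-D intensity grids in [0, 1]."""

    channels: dict  # ordered mapping modality -> 2-D float array in [0, 1]
    label: str
    case_id: str
    pixel_spacing: float = 0.5  # mm per pixel, isotropic
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("SliceStack needs at least one channel")
        shapes = {np.asarray(v).shape for v in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        for name, arr in self.channels.items():
            a = np.asarray(arr)
            if a.ndim != 2:
                raise ValueError(f"channel {name!r} is not 2-D")
            if a.min() < 0 or a.max() > 1:
                raise ValueError(f"channel {name!r} has values outside [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape


@dataclass
class Cohort:
    cases: list
    class_counts: dict
    seed: int

    def __post_init__(self) -> None:
        if sum(self.class_counts.values()) != len(self.cases):
            raise ValueError("class_counts does not sum to len(cases)")
        labels = {c.label for c in self.cases}
        if not labels <= set(self.class_counts):
            raise ValueError("case label missing from class_counts")

    def __len__(self) -> int:
        return len(self.cases)

    @property
    def labels(self) -> list:
        return [c.label for c in self.cases]


@dataclass(frozen=True)
class AugmentConfig:
    """Stochastic augmentation settings: flips, small rotations (±10° by
    default), multiplicative intensity scaling and additive Gaussian noise
    with sigma drawn in [0.01, 0.05]."""

    p_flip_h: float = 0.5
    p_flip_v: float = 0.5
    max_rotation_deg: float = 10.0
    intensity_scale_range: tuple = (0.9, 1.1)
    noise_sigma_range: tuple = (0.01, 0.05)

    def __post_init__(self) -> None:
        for p in (self.p_flip_h, self.p_flip_v):
            if not 0 <= p <= 1:
                raise ValueError("flip probabilities must be in [0, 1]")
        if self.max_rotation_deg < 0:
            raise ValueError("max_rotation_deg must be >= 0")
        lo, hi = self.noise_sigma_range
        if not 0 <= lo <= hi:
            raise ValueError("noise_sigma_range must satisfy 0 <= lo <= hi")
        slo, shi = self.intensity_scale_range
        if not 0 < slo <= shi:
            raise ValueError("intensity_scale_range must satisfy 0 < lo <= hi")


@dataclass
class FeatureFixture:
    """Low-dimensional labelled feature matrix for selector tests."""

    X: np.ndarray
    y: np.ndarray
    informative_idx: set
    effect_size: float
    seed: int


# ---------------------------------------------------------------------------
# size distributions
# ---------------------------------------------------------------------------

def lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of the log-normal whose mean and sd equal the arguments.

    sigma^2 = ln(1 + sd^2/mean^2),  mu = ln(mean) - sigma^2/2.
    """
    if mean <= 0:
        raise ValueError("mean must be > 0")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def draw_volumes(mean: float, sd: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """n positive volume draws from the moment-matched log-normal."""
    mu, sigma = lognormal_params(mean, sd)
    return rng.lognormal(mu, sigma, size=n)


def volume_to_area_cm2(volume_cm3) -> np.ndarray:
    """Great-circle area (cm^2) of the sphere with the given volume."""
    v = np.asarray(volume_cm3, dtype=float)
    return np.pi * (3.0 * v / (4.0 * np.pi)) ** (2.0 / 3.0)


def _area_px(volume_cm3: float, pixel_spacing_mm: float) -> float:
    spacing_cm = pixel_spacing_mm / 10.0
    return float(volume_to_area_cm2(volume_cm3)) / spacing_cm**2


# ---------------------------------------------------------------------------
# phantom rendering
# ---------------------------------------------------------------------------

def _ellipse_mask(shape, center, area_px, aspect, rng=None) -> np.ndarray:
    """Boolean mask of an axis-aligned ellipse with the requested pixel area,
    clipped so its radii fit inside the image."""
    h, w = shape
    r_eq = math.sqrt(max(area_px, 1.0) / math.pi)
    a = r_eq / math.sqrt(aspect)   # semi-axis along rows
    b = r_eq * math.sqrt(aspect)   # semi-axis along cols
    a = min(a, h / 2.5)
    b = min(b, w / 2.5)
    rr, cc = np.ogrid[:h, :w]
    return ((rr - center[0]) / a) ** 2 + ((cc - center[1]) / b) ** 2 <= 1.0


def _smooth_field(shape, scale: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian random field with correlation length ``scale``."""
    raw = rng.standard_normal(shape)
    sm = ndimage.gaussian_filter(raw, sigma=scale)
    sd = sm.std()
    return sm / sd if sd > 0 else sm


def canal_template(size: int, canal_col: int, canal_width: float = 6.0,
                   background: float = 0.15, canal_intensity: float = 0.45) -> np.ndarray:
    """Deterministic background: flat tissue plus a bright vertical canal
    stripe with a Gaussian cross-profile centered on ``canal_col``."""
    cols = np.arange(size, dtype=float)
    profile = canal_intensity * np.exp(-0.5 * ((cols - canal_col) / canal_width) ** 2)
    return np.clip(background + np.tile(profile, (size, 1)), 0.0, 1.0)


def generate_phantom(profile: ClassProfile, size: int = 256,
                     modalities=DEFAULT_MODALITIES, rng_seed: int = 0,
                     pixel_spacing: float = 0.5, noise_sigma: float = 0.02,
                     case_id: str | None = None) -> SliceStack:
    """Render one synthetic axial slice stack for a class profile.

    The slice contains a bright spinal-canal stripe whose column is drawn
    uniformly in the central 50% of columns, a tumor ellipse centered in the
    canal, an edema annulus around the tumor, a cavity ellipse offset by a
    seeded random vector, per-modality contrast gains with a small seeded
    scanner jitter, a smooth texture field, and additive Gaussian noise.
    Deterministic given ``rng_seed``.
    """
    if size < 64:
        raise ValueError("size must be >= 64")
    if not modalities:
        raise ValueError("modalities must be nonempty")
    for m in modalities:
        if m not in _MODALITY_GAIN:
            raise ValueError(f"unknown modality {m!r}; known: {sorted(_MODALITY_GAIN)}")

    rng = np.random.default_rng(rng_seed)

    # canal column uniform in the central 50% of columns
    lo, hi = int(size * 0.25), int(size * 0.75)
    canal_col = int(rng.integers(lo, hi))
    template = canal_template(size, canal_col)

    # component sizes (cm^3 -> pixel areas)
    vols = {c: float(draw_volumes(*profile.component_params(c), 1, rng)[0])
            for c in ("tumor", "edema", "cavity")}
    areas = {c: _area_px(v, pixel_spacing) for c, v in vols.items()}

    # geometry: the analysed axial slice is taken through the lesion, so the
    # tumor sits in the canal near mid-image with small vertical jitter;
    # edema forms an annulus around the tumor; the cavity is syrinx-like — a
    # thin fluid column along the canal, offset up or down the cord by a
    # seeded random vector
    # definite off-center placement: a lesion dead on the quadrant boundary
    # is the degenerate case of quadrant localization
    row_off = rng.uniform(size / 32, size / 8) * (1 if rng.random() < 0.5 else -1)
    tumor_row = int(size / 2 + row_off)
    tumor_center = (tumor_row, canal_col)
    aspect_t = rng.uniform(0.6, 1.0)
    tumor = _ellipse_mask((size, size), tumor_center, areas["tumor"], aspect_t)
    outer = _ellipse_mask((size, size), tumor_center,
                          areas["tumor"] + areas["edema"], aspect_t)
    edema = outer & ~tumor
    sign = 1 if rng.random() < 0.5 else -1
    r_tum = math.sqrt(areas["tumor"] / math.pi)
    cav_semi_col = min(8.0, size / 32)           # thin: canal-width column
    cav_semi_row = min(areas["cavity"] / (math.pi * cav_semi_col), size / 2.5)
    cav_row = tumor_row + sign * (r_tum + rng.uniform(0, size / 16))
    cav_center = (int(np.clip(cav_row, 8, size - 8)), canal_col)
    rr, cc = np.ogrid[:size, :size]
    cavity = (((rr - cav_center[0]) / cav_semi_row) ** 2
              + ((cc - cav_center[1]) / cav_semi_col) ** 2) <= 1.0

    offsets = profile.intensity_offsets
    lesion = np.zeros((size, size))
    lesion[cavity] += offsets.get("cavity", 0.0)
    lesion[edema] += offsets.get("edema", 0.0)
    lesion[tumor] += offsets.get("tumor", 0.0)

    channels = {}
    for m in modalities:
        gain = _MODALITY_GAIN[m] * (1.0 + 0.05 * rng.standard_normal())
        img = template + gain * lesion
        if noise_sigma > 0:
            img = img + 0.6 * noise_sigma * _smooth_field(
                (size, size), profile.texture_scale, rng)
            img = img + rng.normal(0.0, noise_sigma, (size, size))
        channels[m] = np.clip(img, 0.0, 1.0)

    ys, xs = np.nonzero(tumor)
    centroid = (float(ys.mean()), float(xs.mean())) if ys.size else tumor_center
    return SliceStack(
        channels=channels,
        label=profile.name,
        case_id=case_id or f"{profile.name}-{rng_seed}",
        pixel_spacing=pixel_spacing,
        meta={"canal_col": canal_col, "tumor_center": tumor_center,
              "tumor_centroid": centroid, "volumes_cm3": vols,
              "rng_seed": rng_seed},
    )


def generate_cohort(profiles=None, counts=None, base_seed: int = 0,
                    size: int = 256, modalities=DEFAULT_MODALITIES,
                    noise_sigma: float = 0.02) -> Cohort:
    """Generate a cohort with exactly the requested per-class counts.

    Per-case seeds are ``base_seed * 10**6 + case_index``, so cohorts from
    different base seeds never share a case seed at realistic sizes.
    """
    if profiles is None:
        profiles = DEFAULT_PROFILES
    elif not isinstance(profiles, dict):
        profiles = {p.name: p for p in profiles}
    if counts is None:
        counts = {k: DEFAULT_CLASS_COUNTS[k] for k in profiles}

    for cls, n in counts.items():
        if cls not in profiles:
            raise ValueError(f"count key {cls!r} has no matching profile")
        if n < 1:
            raise ValueError(f"count for {cls!r} must be >= 1")

    cases, idx = [], 0
    for cls in counts:
        for j in range(counts[cls]):
            seed_i = base_seed * 10**6 + idx
            cases.append(generate_phantom(
                profiles[cls], size=size, modalities=modalities,
                rng_seed=seed_i, noise_sigma=noise_sigma,
                case_id=f"case{idx:04d}-{cls}"))
            idx += 1
    return Cohort(cases=cases, class_counts=dict(counts), seed=base_seed)


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def augment(stack: SliceStack, cfg: AugmentConfig, rng_seed: int = 0) -> SliceStack:
    """Apply one random augmentation draw: the same flips and rotation to all
    channels, then per-channel intensity scaling and additive Gaussian noise.
    Intensities are re-clipped to [0, 1]; the label is preserved."""
    rng = np.random.default_rng(rng_seed)
    do_h = rng.random() < cfg.p_flip_h
    do_v = rng.random() < cfg.p_flip_v
    angle = (rng.uniform(-cfg.max_rotation_deg, cfg.max_rotation_deg)
             if cfg.max_rotation_deg > 0 else 0.0)
    scale = rng.uniform(*cfg.intensity_scale_range)
    lo, hi = cfg.noise_sigma_range
    sigma = rng.uniform(lo, hi) if hi > 0 else 0.0

    out = {}
    for name, img in stack.channels.items():
        a = np.asarray(img, dtype=float)
        if do_h:
            a = a[:, ::-1]
        if do_v:
            a = a[::-1, :]
        if angle != 0.0:
            a = ndimage.rotate(a, angle, reshape=False, order=1, mode="nearest")
        a = a * scale
        if sigma > 0:
            a = a + rng.normal(0.0, sigma, a.shape)
        out[name] = np.clip(a, 0.0, 1.0)
    return dataclasses.replace(stack, channels=out,
                               meta={**stack.meta, "augment_seed": rng_seed})


# ---------------------------------------------------------------------------
# tabular fixtures for selector tests
# ---------------------------------------------------------------------------

def make_feature_fixture(n_per_class: int, n_classes: int, d_informative: int,
                         d_noise: int, effect_size: float, seed: int = 0
                         ) -> FeatureFixture:
    """Gaussian feature matrix whose first ``d_informative`` columns carry a
    class signal and the rest are standard-normal noise.

    Class means sit on a (centered-identity) simplex arrangement scaled so
    pairwise mean separation equals ``effect_size`` in within-class sd units
    when ``d_informative >= n_classes``; for fewer informative columns the
    simplex coordinates are cycled across columns.
    """
    if n_per_class < 2:
        raise ValueError("n_per_class must be >= 2")
    if d_informative + d_noise < 1:
        raise ValueError("need at least one column")
    if effect_size < 0:
        raise ValueError("effect_size must be >= 0")

    rng = np.random.default_rng(seed)
    n = n_per_class * n_classes
    d = d_informative + d_noise
    y = np.repeat(np.arange(n_classes), n_per_class)

    # centered identity: rows are regular-simplex vertices with edge sqrt(2)
    simplex = np.eye(n_classes) - 1.0 / n_classes
    means = np.zeros((n_classes, d_informative))
    for j in range(d_informative):
        means[:, j] = simplex[:, j % n_classes]
    means *= effect_size / math.sqrt(2.0)

    X = rng.standard_normal((n, d))
    if d_informative:
        X[:, :d_informative] += means[y]
    return FeatureFixture(X=X, y=y, informative_idx=set(range(d_informative)),
                          effect_size=effect_size, seed=seed)
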