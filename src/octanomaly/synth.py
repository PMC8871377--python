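"""Synthetic OCT-like B-scan generator.

Real retinal B-scans show a stack of roughly horizontal bright bands (the
retinal layers) over a dark background, corrupted by multiplicative
speckle.  Dry AMD presents as localized bumps (drusen) on the RPE — the
lowest bright band — while wet AMD shows a dark sub-retinal fluid dome
that lifts the overlying layers.  This module renders those three
morphologies with controllable lesion size and noise level so that every
downstream stage (embedding training, LOF scoring, end-to-end evaluation)
is testable without any external dataset.

Geometry is deliberately simple: band centerlines are smoothed random
walks with a global tilt, drusen are raised-cosine bumps with compact
support, and the fluid pocket is a raised-cosine dome.  Compact supports
mean a lesioned image differs from its paired noise-free normal baseline
*only* inside the recorded lesion intervals, which is what makes the
labels correct by construction.

All randomness flows from ``SynthConfig.seed`` (or an explicit override);
per-image streams are derived by counter-based seed splitting, so the
content of image *i* of a class does not depend on how many images of
other classes were requested.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .data import ImageSet, Label, LabeledImage

BACKGROUND = 0.12
FLUID_INTENSITY = 0.04


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic B-scan generator.

    Distances are in pixels, intensities in ``[0, 1]``.  ``speckle_sd`` is
    the standard deviation of the multiplicative speckle field
    ``pixel * (1 + sd * N(0, 1))``.
    """

    height: int = 224
    width: int = 224
    n_layers: int = 5
    layer_contrast: float = 0.55
    speckle_sd: float = 0.08
    drusen_count: int = 3
    drusen_amplitude: float = 12.0
    drusen_width: float = 18.0
    fluid_depth: float = 40.0
    fluid_width: float = 90.0
    tilt_jitter: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ValueError("height and width must be positive")
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        if not 0.0 <= self.layer_contrast <= 1.0:
            raise ValueError("layer_contrast must lie in [0, 1]")
        if self.speckle_sd < 0:
            raise ValueError("speckle_sd must be >= 0")
        if self.drusen_count < 0:
            raise ValueError("drusen_count must be >= 0")
        if self.drusen_amplitude < 0 or self.fluid_depth < 0:
            raise ValueError("lesion amplitudes must be >= 0")
        if self.drusen_amplitude >= self.height / 4:
            raise ValueError("drusen_amplitude must stay below height/4")
        if self.fluid_depth >= self.height / 3:
            raise ValueError("fluid_depth must stay below height/3")
        if self.fluid_width >= self.width:
            raise ValueError("fluid_width must be smaller than the frame width")

    def with_seed(self, seed: int) -> "SynthConfig":
        return replace(self, seed=seed)


def _rng_for(config: SynthConfig, rng: Optional[np.random.Generator]) -> np.random.Generator:
    if rng is not None:
        return rng
    return np.random.default_rng(np.random.SeedSequence(config.seed))


def _band_centerlines(config: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """Smooth, roughly horizontal centerlines, one row per band (top to bottom)."""
    h, w = config.height, config.width
    top, bottom = 0.30 * h, 0.82 * h
    if config.n_layers == 1:
        centers = np.array([(top + bottom) / 2.0])
    else:
        centers = np.linspace(top, bottom, config.n_layers)
    tilt = rng.uniform(-config.tilt_jitter, config.tilt_jitter)
    x = np.arange(w)
    slope = tilt * (x - w / 2.0) / max(w, 1)
    # shared gentle undulation so bands stay parallel (layers move together)
    wiggle = gaussian_filter1d(rng.standard_normal(w), sigma=w / 8.0, mode="reflect")
    amp = 0.008 * h
    peak = np.max(np.abs(wiggle))
    if peak > 0:
        wiggle = amp * wiggle / peak
    return centers[:, None] + slope[None, :] + wiggle[None, :]


def _render(config: SynthConfig, centerlines: np.ndarray,
            fluid_mask: Optional[np.ndarray] = None) -> np.ndarray:
    """Paint Gaussian-profile bright bands over the dark background."""
    h, w = config.height, config.width
    thickness = max(2.0, h / (4.0 * config.n_layers))
    sigma = thickness / 2.0
    y = np.arange(h, dtype=np.float64)[:, None]
    profile = np.zeros((h, w))
    for cl in centerlines:
        np.maximum(profile, np.exp(-((y - cl[None, :]) ** 2) / (2.0 * sigma**2)), out=profile)
    img = BACKGROUND + config.layer_contrast * profile
    if fluid_mask is not None:
        img[fluid_mask] = FLUID_INTENSITY
    return np.clip(img, 0.0, 1.0)


def _apply_speckle(img: np.ndarray, config: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    if config.speckle_sd == 0:
        return img
    noisy = img * (1.0 + config.speckle_sd * rng.standard_normal(img.shape))
    return np.clip(noisy, 0.0, 1.0)


def _raised_cosine(x: np.ndarray, center: float, width: float, amplitude: float) -> np.ndarray:
    """Smooth bump of compact support ``[center - width/2, center + width/2]``."""
    u = (x - center) / width
    bump = amplitude * np.cos(np.pi * u) ** 2
    bump[np.abs(u) >= 0.5] = 0.0
    return bump


def generate_normal(config: SynthConfig, rng: Optional[np.random.Generator] = None) -> LabeledImage:
    """A healthy layered B-scan: smooth bright bands, no lesion."""
    rng = _rng_for(config, rng)
    centerlines = _band_centerlines(config, rng)
    img = _render(config, centerlines)
    img = _apply_speckle(img, config, rng)
    return LabeledImage(img, Label.NORMAL, meta={"centerlines": centerlines})


def generate_dry_amd(config: SynthConfig, rng: Optional[np.random.Generator] = None) -> LabeledImage:
    """A dry-AMD B-scan: the RPE (lowest band) carries drusen bumps.

    Drusen centers are jittered within equal-width slots across the frame,
    which guarantees the ``drusen_count`` support intervals are disjoint.
    """
    if config.drusen_count < 1:
        raise ValueError("dry AMD requires drusen_count >= 1")
    if config.drusen_amplitude <= 0:
        raise ValueError("dry AMD requires a positive drusen_amplitude")
    rng = _rng_for(config, rng)
    centerlines = _band_centerlines(config, rng)
    baseline_rpe = centerlines[-1].copy()

    w = config.width
    margin = config.drusen_width / 2.0 + 2.0
    usable = w - 2.0 * margin
    if usable <= 0 or usable / config.drusen_count < config.drusen_width:
        raise ValueError("drusen do not fit in the frame without overlapping")
    slot = usable / config.drusen_count
    x = np.arange(w, dtype=np.float64)
    intervals = []
    bumped = centerlines[-1].copy()
    for i in range(config.drusen_count):
        lo = margin + i * slot
        center = lo + config.drusen_width / 2.0 + rng.uniform(0.0, slot - config.drusen_width)
        amp = config.drusen_amplitude * rng.uniform(0.8, 1.0)
        bumped -= _raised_cosine(x, center, config.drusen_width, amp)  # up = smaller row
        intervals.append((center - config.drusen_width / 2.0, center + config.drusen_width / 2.0))
    centerlines[-1] = bumped

    img = _render(config, centerlines)
    img = _apply_speckle(img, config, rng)
    return LabeledImage(
        img,
        Label.DRY_AMD,
        meta={
            "centerlines": centerlines,
            "baseline_rpe": baseline_rpe,
            "drusen_intervals": intervals,
        },
    )


def generate_wet_amd(config: SynthConfig, rng: Optional[np.random.Generator] = None) -> LabeledImage:
    """A wet-AMD B-scan: a dark sub-retinal fluid dome elevates the bands."""
    if config.fluid_depth < 1:
        raise ValueError("wet AMD requires fluid_depth >= 1")
    rng = _rng_for(config, rng)
    centerlines = _band_centerlines(config, rng)
    baseline = centerlines.copy()

    h, w = config.height, config.width
    x = np.arange(w, dtype=np.float64)
    cx = w / 2.0 + rng.uniform(-0.1, 0.1) * w
    dome = _raised_cosine(x, cx, config.fluid_width, config.fluid_depth)
    centerlines = centerlines - dome[None, :]  # all bands lifted together
    if np.min(centerlines) < 1.0:
        raise ValueError("fluid geometry pushes layers out of the frame")

    # fluid fills the gap between the elevated RPE and its flat baseline
    y = np.arange(h, dtype=np.float64)[:, None]
    thickness = max(2.0, h / (4.0 * config.n_layers))
    fluid_mask = (y > centerlines[-1][None, :] + thickness / 2.0) & (
        y < baseline[-1][None, :] + thickness / 2.0
    )

    img = _render(config, centerlines, fluid_mask=fluid_mask)
    img = _apply_speckle(img, config, rng)
    return LabeledImage(
        img,
        Label.WET_AMD,
        meta={
            "centerlines": centerlines,
            "baseline_centerlines": baseline,
            "fluid_center": cx,
            "fluid_interval": (cx - config.fluid_width / 2.0, cx + config.fluid_width / 2.0),
            "fluid_mask": fluid_mask,
        },
    )


_GENERATORS = {
    Label.NORMAL: generate_normal,
    Label.DRY_AMD: generate_dry_amd,
    Label.WET_AMD: generate_wet_amd,
}
_CLASS_ORDER = (Label.NORMAL, Label.DRY_AMD, Label.WET_AMD)


def generate_dataset(
    config: SynthConfig,
    n_per_class: tuple[int, int, int],
    seed: Optional[int] = None,
) -> ImageSet:
    """Generate a shuffled labeled set with exact per-class counts.

    ``n_per_class`` is ``(n_normal, n_dry, n_wet)``.  Image *i* of class *c*
    is produced from seed stream ``SeedSequence(seed, spawn_key=(c, i))``,
    so per-class counts do not perturb other images, and the shuffle has
    its own stream.
    """
    if len(n_per_class) != 3 or any(n < 0 for n in n_per_class):
        raise ValueError("n_per_class must be three non-negative counts")
    base = config.seed if seed is None else seed
    images: list[LabeledImage] = []
    for ci, (label, n) in enumerate(zip(_CLASS_ORDER, n_per_class)):
        gen = _GENERATORS[label]
        for i in range(n):
            ss = np.random.SeedSequence(base, spawn_key=(ci, i))
            img = gen(config, rng=np.random.default_rng(ss))
            img.source = f"{label.value}_{i:05d}.png"
            images.append(img)
    shuffle_rng = np.random.default_rng(np.random.SeedSequence(base, spawn_key=(3, 0)))
    order = shuffle_rng.permutation(len(images))
    return ImageSet([images[i] for i in order])
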