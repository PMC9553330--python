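"""Phantom breast-DWI generator.

Produces two-b-value diffusion-weighted slices (b = 0 and 850 s/mm^2 by
default, 256x256 matrix) containing a single irregular tumor with a known
ground-truth mask and a Ki-67 expression class.  Tumor ADC is drawn from a
class-conditional normal: high-Ki-67 lesions are more cellular and diffuse
less, so their ADC is lower.  The defaults (0.82 +/- 0.08 vs
0.98 +/- 0.15, in units of 1e-3 mm^2/s) encode that contrast.

Signal follows the mono-exponential model S_b = S_0 * exp(-b * ADC).
Background fibroglandular tissue gets a higher ADC (~1.8e-3 mm^2/s) with
smooth spatial heterogeneity, so tumors are markedly hyperintense on the
high-b image -- the contrast the downstream segmenter learns.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .exceptions import ParameterError

__all__ = [
    "AcquisitionProfile",
    "ClassAdcModel",
    "Sample",
    "Dataset",
    "simulate_tumor_mask",
    "dwi_signal",
    "simulate_case",
    "simulate_dataset",
]

HIGH, LOW = "high", "low"
#: ADC values are clipped below this floor (mm^2/s) to keep exp(-b*ADC) sane.
ADC_FLOOR = 0.1e-3


@dataclass(frozen=True)
class AcquisitionProfile:
    """Emulated DWI acquisition geometry and diffusion weightings."""

    b_values: tuple[float, ...] = (0.0, 850.0)
    matrix_size: int = 256
    pixel_spacing_mm: float = 0.7

    def __post_init__(self) -> None:
        object.__setattr__(self, "b_values", tuple(float(b) for b in self.b_values))
        if any(b < 0 for b in self.b_values):
            raise ParameterError("b_values must be non-negative")
        if any(b2 <= b1 for b1, b2 in zip(self.b_values, self.b_values[1:])):
            raise ParameterError("b_values must be strictly increasing")
        if self.matrix_size < 32:
            raise ParameterError("matrix_size must be >= 32")
        if self.pixel_spacing_mm <= 0:
            raise ParameterError("pixel_spacing_mm must be > 0")


@dataclass(frozen=True)
class ClassAdcModel:
    """Class-conditional tumor ADC distributions (mm^2/s)."""

    mean_high: float = 0.82e-3
    sd_high: float = 0.08e-3
    mean_low: float = 0.98e-3
    sd_low: float = 0.15e-3

    def __post_init__(self) -> None:
        for name in ("mean_high", "sd_high", "mean_low", "sd_low"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        if self.mean_high >= self.mean_low:
            raise ParameterError(
                "mean_high must be < mean_low (higher Ki-67 implies lower ADC)"
            )

    def params_for(self, ki67_class: str) -> tuple[float, float]:
        if ki67_class == HIGH:
            return self.mean_high, self.sd_high
        if ki67_class == LOW:
            return self.mean_low, self.sd_low
        raise ParameterError(f"unknown Ki-67 class {ki67_class!r}")


@dataclass
class Sample:
    """One phantom case: per-b-value images, mask, class label, true ADC."""

    case_id: str
    images: tuple[np.ndarray, ...]
    mask: np.ndarray
    b_values: tuple[float, ...]
    spacing: float
    ki67_class: str
    true_adc: float

    def __post_init__(self) -> None:
        shapes = {im.shape for im in self.images} | {self.mask.shape}
        if len(shapes) != 1:
            raise ParameterError("all images and the mask must share one shape")
        if not np.isin(self.mask, (0, 1)).all():
            raise ParameterError("mask must be binary")
        if not self.mask.any():
            raise ParameterError("mask must be nonempty")
        if self.true_adc <= 0:
            raise ParameterError("true_adc must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


@dataclass
class Dataset:
    """Ordered collection of samples generated from one master seed."""

    samples: list[Sample]
    seed: int
    profile: AcquisitionProfile = field(default_factory=AcquisitionProfile)

    def __post_init__(self) -> None:
        if not self.samples:
            raise ParameterError("Dataset must be non-empty")
        if len({s.shape for s in self.samples}) != 1:
            raise ParameterError("all samples must share one matrix size")

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    def __getitem__(self, i):
        if isinstance(i, slice):
            return replace(self, samples=self.samples[i])
        return self.samples[i]

    def labels(self) -> list[str]:
        return [s.ki67_class for s in self.samples]


def simulate_tumor_mask(
    matrix_size: int,
    rng_seed,
    area_fraction: tuple[float, float] = (0.01, 0.08),
    irregularity: float = 0.15,
    aspect_range: tuple[float, float] = (0.7, 1.3),
) -> np.ndarray:
    """Rasterize a randomly perturbed ellipse as a binary tumor mask.

    The lesion is star-convex: radius r(theta) = r0 * (1 + sum_k a_k
    cos(k theta + phi_k)) for harmonics k = 2..5 with amplitudes bounded by
    ``irregularity``, stretched anisotropically and rotated.  The rasterized
    area is driven into ``area_fraction`` of the image by rescaling r0, and
    the lesion stays at least one pixel clear of the border.
    """
    if matrix_size < 32:
        raise ParameterError("matrix_size must be >= 32")
    lo, hi = area_fraction
    if lo > hi or lo <= 0:
        raise ParameterError("area_fraction bounds must satisfy 0 < min <= max")
    rng = np.random.default_rng(rng_seed)

    target_frac = rng.uniform(lo, hi)
    aspect = rng.uniform(*aspect_range)
    rot = rng.uniform(0, np.pi)
    amps = rng.uniform(0, irregularity, size=4) / np.arange(1, 5)
    phases = rng.uniform(0, 2 * np.pi, size=4)
    # ellipse with semi-axes r0*aspect, r0/aspect has area pi*r0^2
    r0 = np.sqrt(target_frac * matrix_size**2 / np.pi)

    margin = 2.0  # px clearance from the border
    rmax = r0 * (1 + amps.sum()) * max(aspect, 1 / aspect)
    c_lo, c_hi = margin + rmax, matrix_size - 1 - margin - rmax
    if c_lo >= c_hi:  # lesion too large to float freely: centre it
        cy = cx = (matrix_size - 1) / 2.0
    else:
        cy, cx = rng.uniform(c_lo, c_hi, size=2)

    yy, xx = np.mgrid[0:matrix_size, 0:matrix_size].astype(np.float64)
    dy, dx = yy - cy, xx - cx
    # rotate then stretch into the unit-circle frame of the ellipse
    ry = (np.cos(rot) * dy + np.sin(rot) * dx) / aspect
    rx = (-np.sin(rot) * dy + np.cos(rot) * dx) * aspect
    rad = np.hypot(ry, rx)
    theta = np.arctan2(ry, rx)
    boundary = 1.0 + sum(
        a * np.cos((k + 2) * theta + p) for k, (a, p) in enumerate(zip(amps, phases))
    )

    scale = 1.0
    for _ in range(40):  # drive rasterized area into the requested bounds
        mask = (rad <= scale * r0 * boundary).astype(np.uint8)
        mask[0, :] = mask[-1, :] = mask[:, 0] = mask[:, -1] = 0
        frac = mask.sum() / matrix_size**2
        if lo <= frac <= hi and mask.any():
            break
        scale *= np.sqrt(target_frac / max(frac, 1.0 / matrix_size**2))
    else:
        raise ParameterError("could not rasterize a mask within the area bounds")

    lab, n = ndimage.label(mask)
    if n > 1:  # harmonics can pinch off slivers; keep the largest component
        sizes = ndimage.sum_labels(mask, lab, index=range(1, n + 1))
        mask = (lab == 1 + int(np.argmax(sizes))).astype(np.uint8)
    return mask


def dwi_signal(s0, b, adc):
    """Mono-exponential DWI signal: s0 * exp(-b * adc)."""
    s0, b, adc = np.asarray(s0, float), np.asarray(b, float), np.asarray(adc, float)
    if (np.asarray(s0) < 0).any():
        raise ParameterError("s0 must be >= 0")
    if (b < 0).any():
        raise ParameterError("b must be >= 0")
    if (adc <= 0).any():
        raise ParameterError("adc must be > 0")
    out = s0 * np.exp(-b * adc)
    return float(out) if out.ndim == 0 else out


def _smooth_field(rng: np.random.Generator, size: int, corr_px: float) -> np.ndarray:
    """Zero-mean, unit-sd smooth random field (low-frequency heterogeneity)."""
    f = ndimage.gaussian_filter(rng.standard_normal((size, size)), corr_px)
    sd = f.std()
    return f / sd if sd > 0 else f


def simulate_case(
    ki67_class: str,
    profile: AcquisitionProfile | None = None,
    adc_model: ClassAdcModel | None = None,
    rng_seed=0,
    *,
    case_id: str | None = None,
    s0_background: float = 60.0,
    s0_tumor: float = 85.0,
    background_adc: float = 1.8e-3,
    background_adc_sd: float = 0.2e-3,
    noise_sd: float = 3.0,
) -> Sample:
    """Simulate one case of the given Ki-67 class.

    Tumor ADC ~ N(class mean, class sd) clipped at ``ADC_FLOOR``; background
    ADC varies smoothly around ``background_adc``.  One magnitude image per
    b-value, with additive Gaussian noise.
    """
    profile = profile or AcquisitionProfile()
    adc_model = adc_model or ClassAdcModel()
    mean, sd = adc_model.params_for(ki67_class)  # validates the class label
    rng = np.random.default_rng(rng_seed)

    n = profile.matrix_size
    mask = simulate_tumor_mask(n, rng.integers(2**31))
    true_adc = float(max(rng.normal(mean, sd), ADC_FLOOR))

    # smooth S0 and ADC maps; tumor slightly hyperintense on S0 and sharply
    # restricted (low ADC) relative to background tissue
    s0_map = s0_background * (1 + 0.15 * _smooth_field(rng, n, n / 8))
    s0_map = np.where(mask, s0_tumor * (1 + 0.05 * _smooth_field(rng, n, n / 16)), s0_map)
    adc_map = background_adc + background_adc_sd * _smooth_field(rng, n, n / 8)
    adc_map = np.where(mask, true_adc * (1 + 0.05 * _smooth_field(rng, n, n / 16)), adc_map)
    adc_map = np.maximum(adc_map, ADC_FLOOR)
    s0_map = np.maximum(s0_map, 0.0)

    images = []
    for b in profile.b_values:
        img = dwi_signal(s0_map, b, adc_map) + noise_sd * rng.standard_normal((n, n))
        images.append(np.maximum(img, 0.0).astype(np.float32))

    return Sample(
        case_id=case_id or f"case_{ki67_class}_{rng_seed}",
        images=tuple(images),
        mask=mask,
        b_values=profile.b_values,
        spacing=profile.pixel_spacing_mm,
        ki67_class=ki67_class,
        true_adc=true_adc,
    )


def case_seed(master_seed: int, index: int) -> int:
    """Deterministic per-case seed derived from the master seed."""
    return int(np.random.SeedSequence([int(master_seed), int(index)]).generate_state(1)[0])


def simulate_dataset(
    n_high: int,
    n_low: int,
    profile: AcquisitionProfile | None = None,
    adc_model: ClassAdcModel | None = None,
    seed: int = 0,
    **case_kwargs,
) -> Dataset:
    """Simulate a cohort with ``n_high`` high- and ``n_low`` low-Ki-67 cases.

    Classes are interleaved proportionally so any contiguous split stays
    roughly stratified; per-case seeds derive deterministically from ``seed``.
    """
    if n_high < 0 or n_low < 0 or n_high + n_low < 1:
        raise ParameterError("need n_high + n_low >= 1 with non-negative counts")
    profile = profile or AcquisitionProfile()
    adc_model = adc_model or ClassAdcModel()

    classes = [HIGH] * n_high + [LOW] * n_low
    order = np.random.default_rng(np.random.SeedSequence([int(seed), 0xC0FFEE]))
    order.shuffle(classes)

    samples = [
        simulate_case(
            cls,
            profile,
            adc_model,
            rng_seed=case_seed(seed, i),
            case_id=f"case_{i:04d}",
            **case_kwargs,
        )
        for i, cls in enumerate(classes)
    ]
    return Dataset(samples=samples, seed=seed, profile=profile)
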