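"""Seeded synthetic fluorescence-microscopy generator with exported ground truth.

Emulates confocal images of adherent cells as used for membrane-recruitment
quantification: a bright plasma-membrane rim of constant width, a dimmer
cytoplasm fill, dark background, photon (Poisson) noise with optional
Gaussian read noise, optional membrane puncta, correlated dual-channel
membrane signal, and time-lapse membrane-intensity decay after hyposmotic
shock. Every generator is deterministic for a fixed seed and returns the
ground truth (masks, true M-C ratio, true trace, true channel correlation)
needed to validate the analysis stages.

Cell geometry is an ellipse whose boundary radius is perturbed by a
low-order sinusoid, giving mildly irregular but convex-ish outlines. The
membrane rim is the band of ``membrane_rim_width`` pixels immediately
inside the cell boundary (footprint minus its morphological erosion); the
cytoplasm is everything deeper inside. Optics (PSF blur, z-sectioning) are
deliberately not simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import Image2D, ImageMeta, TimeLapse

__all__ = [
    "SyntheticCellSpec",
    "GroundTruth",
    "ShockTraceModel",
    "generate_cell_image",
    "generate_population",
    "generate_shock_stack",
    "generate_dual_channel",
    "generate_coexpression_population",
]

_NOISE_MODELS = ("none", "poisson", "gaussian", "poisson+gaussian")

#: number of sinusoidal lobes perturbing the ellipse boundary
_IRREGULARITY_ORDER = 3


@dataclass
class SyntheticCellSpec:
    """Geometry and photometry of one synthetic cell.

    Intensities are in arbitrary units (a.u.) matching the detector scale
    of the emulated 16-bit images; the defaults give a cell with a clear
    rim (M-C ratio 3) well above background.
    """

    center: tuple[float, float] = (256.0, 256.0)  # (x, y) pixels
    semi_axes: tuple[float, float] = (120.0, 90.0)  # (a, b) pixels
    boundary_irregularity: float = 0.05  # unitless radial amplitude
    membrane_rim_width: int = 5  # pixels
    membrane_intensity: float = 300.0  # a.u.
    cytoplasm_intensity: float = 100.0  # a.u.
    background_intensity: float = 5.0  # a.u.
    noise_model: str = "poisson"  # one of none|poisson|gaussian|poisson+gaussian
    read_noise_sd: float = 0.0  # a.u., gaussian component
    puncta_count: int = 0
    puncta_intensity: float = 0.0  # a.u., peak amplitude added on the rim
    puncta_sigma: float = 1.5  # pixels

    def __post_init__(self) -> None:
        if self.membrane_rim_width < 1:
            raise ValueError("membrane_rim_width must be >= 1 pixel")
        for name in ("membrane_intensity", "cytoplasm_intensity",
                     "background_intensity", "puncta_intensity"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.boundary_irregularity < 0:
            raise ValueError("boundary_irregularity must be >= 0")
        if self.noise_model not in _NOISE_MODELS:
            raise ValueError(f"noise_model must be one of {_NOISE_MODELS}")
        if self.puncta_count < 0:
            raise ValueError("puncta_count must be >= 0")


@dataclass
class GroundTruth:
    """What the generator actually rendered, for validating the analysis."""

    membrane_mask: np.ndarray  # boolean, rim band
    cytoplasm_mask: np.ndarray  # boolean, interior
    true_mc_ratio: float
    true_localization: str  # "PM" or "Cyt"
    seed: int
    footprint_mask: np.ndarray | None = None
    channel_rho: float | None = None  # dual-channel target correlation

    def __post_init__(self) -> None:
        if np.any(self.membrane_mask & self.cytoplasm_mask):
            raise ValueError("membrane and cytoplasm masks must be disjoint")


@dataclass
class ShockTraceModel:
    """True membrane-intensity time course after hyposmotic shock.

    ``plateau``: intensity ramps down linearly over ``time_constant``
    seconds after the shock and then stays at
    ``pre_level * (1 - drop_fraction)`` — the behaviour of lipid-anchored
    proteins whose release levels off. ``gradual``: intensity declines at
    a constant ``slope`` (a.u./s) for the rest of the movie and never
    levels off — the behaviour of a curvature sensor that keeps
    detaching. ``noise_sd`` adds per-frame Gaussian jitter to the
    membrane level before rendering.
    """

    shape: str = "plateau"  # "plateau" or "gradual"
    pre_level: float = 300.0  # a.u.
    drop_fraction: float = 0.5  # plateau shape, in [0, 1]
    time_constant: float = 90.0  # s, ramp duration (plateau shape)
    slope: float = 0.5  # a.u./s decline (gradual shape)
    noise_sd: float = 0.0  # a.u.

    def __post_init__(self) -> None:
        if self.shape not in ("plateau", "gradual"):
            raise ValueError("shape must be 'plateau' or 'gradual'")
        if self.pre_level <= 0:
            raise ValueError("pre_level must be positive")
        if not 0.0 <= self.drop_fraction <= 1.0:
            raise ValueError("drop_fraction must lie in [0, 1]")

    def level_at(self, t_after_shock: float) -> float:
        """Noiseless membrane intensity at ``t_after_shock`` seconds (<=0: pre-shock)."""
        if t_after_shock <= 0:
            return self.pre_level
        if self.shape == "plateau":
            frac = min(t_after_shock / self.time_constant, 1.0) if self.time_constant > 0 else 1.0
            return self.pre_level * (1.0 - self.drop_fraction * frac)
        return max(self.pre_level - self.slope * t_after_shock, 0.0)


def _boundary_radius(theta: np.ndarray, spec: SyntheticCellSpec) -> np.ndarray:
    a, b = spec.semi_axes
    r_ellipse = (a * b) / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)
    return r_ellipse * (1.0 + spec.boundary_irregularity
                        * np.sin(_IRREGULARITY_ORDER * theta))


def _footprint(spec: SyntheticCellSpec, meta: ImageMeta) -> np.ndarray:
    cx, cy = spec.center
    max_r = max(spec.semi_axes) * (1.0 + spec.boundary_irregularity)
    if (cx - max_r < 0 or cx + max_r > meta.width - 1
            or cy - max_r < 0 or cy + max_r > meta.height - 1):
        raise ValueError(
            f"cell geometry (center {spec.center}, max radius {max_r:.1f} px) "
            f"exceeds image bounds {meta.width}x{meta.height}"
        )
    yy, xx = np.mgrid[0:meta.height, 0:meta.width]
    dx = xx - cx
    dy = yy - cy
    rho = np.hypot(dx, dy)
    theta = np.arctan2(dy, dx)
    return rho <= _boundary_radius(theta, spec)


def _rim_split(footprint: np.ndarray, rim_width: int) -> tuple[np.ndarray, np.ndarray]:
    """Split a footprint into (rim band of rim_width px, deeper interior) by depth."""
    depth = ndimage.distance_transform_edt(footprint)
    interior = depth > rim_width
    rim = footprint & ~interior
    if not rim.any() or not interior.any():
        raise ValueError("cell too small: rim or interior is empty")
    return rim, interior


def _render_base(spec: SyntheticCellSpec, meta: ImageMeta,
                 footprint: np.ndarray, rim: np.ndarray, interior: np.ndarray,
                 membrane_level: float | None = None) -> np.ndarray:
    img = np.full(meta.shape, spec.background_intensity, dtype=float)
    img[interior] = spec.cytoplasm_intensity
    img[rim] = spec.membrane_intensity if membrane_level is None else membrane_level
    return img


def _add_puncta(img: np.ndarray, spec: SyntheticCellSpec, rim: np.ndarray,
                rng: np.random.Generator) -> None:
    if spec.puncta_count == 0 or spec.puncta_intensity == 0:
        return
    rim_coords = np.argwhere(rim)
    idx = rng.choice(len(rim_coords), size=spec.puncta_count, replace=False)
    yy, xx = np.mgrid[0:img.shape[0], 0:img.shape[1]]
    for y0, x0 in rim_coords[idx]:
        img += spec.puncta_intensity * np.exp(
            -((yy - y0) ** 2 + (xx - x0) ** 2) / (2.0 * spec.puncta_sigma ** 2)
        )


def _apply_noise(img: np.ndarray, spec: SyntheticCellSpec,
                 rng: np.random.Generator) -> np.ndarray:
    out = img
    if spec.noise_model in ("poisson", "poisson+gaussian"):
        out = rng.poisson(out).astype(float)
    if spec.noise_model in ("gaussian", "poisson+gaussian") and spec.read_noise_sd > 0:
        out = out + rng.normal(0.0, spec.read_noise_sd, size=out.shape)
    return np.clip(out, 0.0, None)


def generate_cell_image(spec: SyntheticCellSpec, meta: ImageMeta | None = None,
                        seed: int = 0) -> tuple[Image2D, GroundTruth]:
    """Render one cell and return the image with its ground truth.

    Deterministic for a fixed seed. With ``noise_model='none'`` the mean
    pixel value over each ground-truth mask equals the specified region
    intensity exactly (no puncta).
    """
    meta = meta or ImageMeta()
    rng = np.random.default_rng(seed)
    footprint = _footprint(spec, meta)
    rim, interior = _rim_split(footprint, spec.membrane_rim_width)
    img = _render_base(spec, meta, footprint, rim, interior)
    _add_puncta(img, spec, rim, rng)
    img = _apply_noise(img, spec, rng)
    ratio = (spec.membrane_intensity / spec.cytoplasm_intensity
             if spec.cytoplasm_intensity > 0 else float("inf"))
    gt = GroundTruth(
        membrane_mask=rim, cytoplasm_mask=interior,
        true_mc_ratio=ratio,
        true_localization="PM" if ratio >= 1.2 else "Cyt",
        seed=seed, footprint_mask=footprint,
    )
    return Image2D(img, meta), gt


def _parse_ratio_distribution(ratio_distribution):
    """Accept a plain number (fixed ratio) or ('lognormal', mu, sigma)."""
    if isinstance(ratio_distribution, (int, float)):
        value = float(ratio_distribution)
        if value <= 0:
            raise ValueError("fixed M-C ratio must be positive")
        return lambda rng, n: np.full(n, value)
    try:
        tag, mu, sigma = ratio_distribution
    except (TypeError, ValueError):
        raise ValueError(
            "ratio_distribution must be a number or ('lognormal', mu, sigma)"
        ) from None
    if tag != "lognormal":
        raise ValueError(f"unknown ratio distribution {tag!r}")
    mu, sigma = float(mu), float(sigma)
    if sigma < 0:
        raise ValueError("lognormal sigma must be >= 0")
    return lambda rng, n: rng.lognormal(mu, sigma, size=n)


def generate_population(n_cells: int, ratio_distribution=2.0,
                        meta: ImageMeta | None = None, seed: int = 0,
                        spec: SyntheticCellSpec | None = None,
                        ) -> list[tuple[Image2D, GroundTruth]]:
    """Generate a population of single-cell images with known true M-C ratios.

    One cell per image; per-cell true ratios are either a fixed value or
    drawn lognormally (the ratio distribution across a transfected cell
    population is right-skewed). Geometry is jittered per cell. Stands in
    for independent biological replicates when real images are unavailable.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    meta = meta or ImageMeta()
    base = spec or SyntheticCellSpec(
        center=(meta.width / 2, meta.height / 2),
        semi_axes=(meta.width * 0.23, meta.height * 0.18),
    )
    draw = _parse_ratio_distribution(ratio_distribution)
    master = np.random.default_rng(seed)
    ratios = draw(master, n_cells)
    cell_seeds = master.integers(0, 2**31 - 1, size=n_cells)
    out = []
    for i in range(n_cells):
        rng = np.random.default_rng(cell_seeds[i])
        jitter = 1.0 + rng.uniform(-0.15, 0.15, size=2)
        cell = replace(
            base,
            semi_axes=(base.semi_axes[0] * jitter[0], base.semi_axes[1] * jitter[1]),
            membrane_intensity=base.cytoplasm_intensity * ratios[i],
        )
        out.append(generate_cell_image(cell, meta, seed=int(cell_seeds[i])))
    return out


def generate_shock_stack(spec: SyntheticCellSpec, model: ShockTraceModel,
                         protocol, seed: int = 0,
                         meta: ImageMeta | None = None,
                         ) -> tuple[TimeLapse, np.ndarray, GroundTruth]:
    """Render a hyposmotic-shock movie and the true noiseless membrane trace.

    Frames are taken every ``protocol.frame_interval`` seconds starting at
    t = 0; the shock occurs after ``protocol.pre_shock_duration``, so the
    pre-shock window contains at least three frames. The returned true
    trace is the noiseless integrated rim intensity per frame
    (membrane level x number of rim pixels).
    """
    meta = meta or ImageMeta()
    times = protocol.frame_times()
    if len(times) < 4:
        raise ValueError("protocol must yield at least 4 frames (3 pre-shock + post)")
    rng = np.random.default_rng(seed)
    footprint = _footprint(spec, meta)
    rim, interior = _rim_split(footprint, spec.membrane_rim_width)
    n_rim = int(rim.sum())
    levels = np.array([model.level_at(t - protocol.pre_shock_duration) for t in times])
    true_trace = levels * n_rim
    frames = np.empty((len(times), *meta.shape))
    for i, level in enumerate(levels):
        noisy_level = level + (rng.normal(0.0, model.noise_sd) if model.noise_sd > 0 else 0.0)
        frame = _render_base(spec, meta, footprint, rim, interior,
                             membrane_level=max(noisy_level, 0.0))
        frames[i] = _apply_noise(frame, spec, rng)
    stack = TimeLapse(frames, times, meta, protocol.frame_interval)
    ratio = (spec.membrane_intensity / spec.cytoplasm_intensity
             if spec.cytoplasm_intensity > 0 else float("inf"))
    gt = GroundTruth(rim, interior, ratio, "PM" if ratio >= 1.2 else "Cyt",
                     seed, footprint_mask=footprint)
    return stack, true_trace, gt


def generate_dual_channel(spec: SyntheticCellSpec, rho: float,
                          meta: ImageMeta | None = None, seed: int = 0,
                          rim_fluctuation_cv: float = 0.25,
                          ) -> tuple[tuple[Image2D, Image2D], GroundTruth]:
    """Render two channels whose membrane-pixel intensities correlate at ``rho``.

    Rim fluctuations are a correlated bivariate Gaussian around the
    specified membrane intensity (coefficient of variation
    ``rim_fluctuation_cv``); cytoplasm and background are rendered
    independently per channel. With ``noise_model='none'`` and rho = +/-1,
    channel 2's rim pixels are an exact affine function of channel 1's.
    """
    if not -1.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [-1, 1]")
    meta = meta or ImageMeta()
    rng = np.random.default_rng(seed)
    footprint = _footprint(spec, meta)
    rim, interior = _rim_split(footprint, spec.membrane_rim_width)
    n = int(rim.sum())
    sd = rim_fluctuation_cv * spec.membrane_intensity
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    rim1 = spec.membrane_intensity + sd * z1
    rim2 = spec.membrane_intensity + sd * (rho * z1 + np.sqrt(1.0 - rho**2) * z2)
    imgs = []
    for rim_vals in (rim1, rim2):
        img = _render_base(spec, meta, footprint, rim, interior)
        img[rim] = np.clip(rim_vals, 0.0, None)
        imgs.append(Image2D(_apply_noise(img, spec, rng), meta))
    ratio = (spec.membrane_intensity / spec.cytoplasm_intensity
             if spec.cytoplasm_intensity > 0 else float("inf"))
    gt = GroundTruth(rim, interior, ratio, "PM" if ratio >= 1.2 else "Cyt",
                     seed, footprint_mask=footprint, channel_rho=rho)
    return (imgs[0], imgs[1]), gt


def generate_coexpression_population(n_cells: int,
                                     expression_range: tuple[float, float] = (0.0, 65000.0),
                                     mc_slope: float = -2e-5,
                                     noise_sd: float = 0.1,
                                     seed: int = 0,
                                     baseline_mc_ratio: float = 2.5,
                                     ) -> pd.DataFrame:
    """Simulate the co-expression experiment: M-C ratio linear in expression level.

    Per-cell expression levels (a.u.) are drawn uniformly over
    ``expression_range`` (the default spans all four analysis bins up to
    65,000 a.u.); the true M-C ratio is
    ``baseline_mc_ratio + mc_slope * expression`` and the measured ratio
    adds Gaussian noise of ``noise_sd``. Returns a table with columns
    cell_id, expression_level, true_mc_ratio, mc_ratio.
    """
    if n_cells < 10:
        raise ValueError("n_cells must be >= 10")
    lo, hi = expression_range
    if not hi > lo >= 0:
        raise ValueError("expression_range must satisfy 0 <= lo < hi")
    rng = np.random.default_rng(seed)
    expr = rng.uniform(lo, hi, size=n_cells)
    true_ratio = baseline_mc_ratio + mc_slope * expr
    if np.any(true_ratio <= 0):
        raise ValueError("mc_slope/baseline combination yields non-positive true ratios")
    measured = true_ratio + (rng.normal(0.0, noise_sd, size=n_cells) if noise_sd > 0 else 0.0)
    return pd.DataFrame({
        "cell_id": np.arange(1, n_cells + 1),
        "expression_level": expr,
        "true_mc_ratio": true_ratio,
        "mc_ratio": measured,
    })
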