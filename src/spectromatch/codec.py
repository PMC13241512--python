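"""Fixed-length numeric representations of spectra.

Each modality is mapped onto a fixed grid before encoding:

* ¹³C NMR  — binary presence vector, 512 bins over 0–300 ppm
  (bin width 300/512 ≈ 0.59 ppm).
* ¹H NMR   — length-10,000 intensity vector over −2 to 10 ppm,
  min-max scaled to [0, 1].
* IR       — length-1600 transmittance vector over 600–3800 cm⁻¹
  (2 cm⁻¹ per element), min-max scaled to [0, 1].
* HSQC     — 512 × 512 grid (¹³C × ¹H axes), peaks rendered as 2-D
  Gaussians from centroid/min/max peak descriptions, max-normalised.

Axes are stored in increasing physical units; the NMR convention of
plotting shift decreasing to the right is a presentation concern only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "PeakList1D",
    "HSQCPeak",
    "SpectrumVector",
    "AugmentationConfig",
    "CodecConfig",
    "bin_c13",
    "vectorize_h1",
    "render_ir",
    "vectorize_ir",
    "rasterize_hsqc",
    "resample_linear",
    "augment_h1",
    "minmax01",
]

C13_RANGE = (0.0, 300.0)
C13_BINS = 512
H1_RANGE = (-2.0, 10.0)
H1_LEN = 10_000
IR_RANGE = (600.0, 3800.0)
IR_LEN = 1600
IR_STEP = 2.0  # cm^-1 per element
HSQC_SHAPE = (512, 512)  # (13C axis rows, 1H axis cols)


@dataclass(frozen=True)
class PeakList1D:
    """A 1-D peak list: positions (ppm or cm⁻¹), intensities, widths (FWHM)."""

    modality: str  # "c13" | "h1" | "ir"
    positions: np.ndarray = field(default_factory=lambda: np.empty(0))
    intensities: np.ndarray = field(default_factory=lambda: np.empty(0))
    widths: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self):
        for name in ("positions", "intensities", "widths"):
            object.__setattr__(self, name, np.atleast_1d(np.asarray(getattr(self, name), dtype=float)))
        if not (len(self.positions) == len(self.intensities) == len(self.widths)):
            raise ValueError("positions, intensities and widths must have equal length")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("peak positions must be finite")
        if np.any(self.intensities < 0) or np.any(self.widths < 0):
            raise ValueError("intensities and widths must be non-negative")

    def __len__(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class HSQCPeak:
    """One C–H correlation peak: centroid and extent on both axes (ppm)."""

    c_centroid: float
    c_min: float
    c_max: float
    h_centroid: float
    h_min: float
    h_max: float

    def __post_init__(self):
        if not (self.c_min <= self.c_centroid <= self.c_max):
            raise ValueError("c_min <= c_centroid <= c_max violated")
        if not (self.h_min <= self.h_centroid <= self.h_max):
            raise ValueError("h_min <= h_centroid <= h_max violated")


@dataclass(frozen=True)
class SpectrumVector:
    """Fixed-length numeric encoding of one modality."""

    modality: str  # "c13" | "h1" | "ir" | "hsqc"
    values: np.ndarray
    axis_lo: float
    axis_hi: float
    units: str

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        expected = {
            "c13": (C13_BINS,),
            "h1": (H1_LEN,),
            "ir": (IR_LEN,),
            "hsqc": HSQC_SHAPE,
        }
        if self.modality in expected and self.values.shape != expected[self.modality]:
            raise ValueError(
                f"{self.modality} vector must have shape {expected[self.modality]}, "
                f"got {self.values.shape}"
            )


@dataclass(frozen=True)
class AugmentationConfig:
    """Noise model for realistic-looking synthetic spectra.

    All scales are >= 0; zero everywhere is the identity. The same seed and
    config always produce the same augmented output.
    """

    position_jitter: float = 0.01  # ppm, std of zero-mean shift noise
    width_broadening: float = 1.1  # multiplicative factor on peak widths
    noise_scale: float = 0.01  # additive noise, fraction of max intensity
    baseline_drift: float = 0.02  # slow sinusoidal drift, fraction of max
    seed: int = 0

    def __post_init__(self):
        for name in ("position_jitter", "noise_scale", "baseline_drift"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.width_broadening < 0:
            raise ValueError("width_broadening must be >= 0")

    @classmethod
    def identity(cls, seed: int = 0) -> "AugmentationConfig":
        return cls(position_jitter=0.0, width_broadening=1.0,
                   noise_scale=0.0, baseline_drift=0.0, seed=seed)

    def with_seed(self, seed: int) -> "AugmentationConfig":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class CodecConfig:
    """Axis ranges and vector lengths for all modalities."""

    c13_bins: int = C13_BINS
    c13_range: tuple[float, float] = C13_RANGE
    h1_len: int = H1_LEN
    h1_range: tuple[float, float] = H1_RANGE
    ir_len: int = IR_LEN
    ir_range: tuple[float, float] = IR_RANGE
    hsqc_shape: tuple[int, int] = HSQC_SHAPE
    h1_lineshape: str = "lorentzian"  # or "gaussian"


def minmax01(values: np.ndarray) -> np.ndarray:
    """Min-max scale to [0, 1]; a constant input maps to all zeros."""
    values = np.asarray(values, dtype=float)
    lo, hi = values.min(), values.max()
    if hi == lo:
        logger.warning("degenerate min-max scaling (constant input); returning zeros")
        return np.zeros_like(values)
    return (values - lo) / (hi - lo)


def bin_c13(peaks: PeakList1D, config: CodecConfig | None = None) -> SpectrumVector:
    """Binary positional encoding of ¹³C shifts over 0–300 ppm.

    Shifts outside the range are dropped (logged); a shift exactly at the
    upper edge clamps into the last bin.
    """
    cfg = config or CodecConfig()
    if peaks.modality != "c13":
        raise ValueError(f"expected c13 peak list, got {peaks.modality}")
    lo, hi = cfg.c13_range
    n = cfg.c13_bins
    width = (hi - lo) / n
    values = np.zeros(n)
    for shift in peaks.positions:
        if shift < lo or shift > hi:
            logger.warning("dropping out-of-range 13C shift %.2f ppm", shift)
            continue
        idx = min(int((shift - lo) // width), n - 1)
        values[idx] = 1.0
    return SpectrumVector("c13", values, lo, hi, "ppm")


def _render_peaks_1d(grid: np.ndarray, peaks: PeakList1D, lineshape: str) -> np.ndarray:
    out = np.zeros_like(grid)
    min_width = 2.0 * (grid[1] - grid[0])
    for pos, inten, width in zip(peaks.positions, peaks.intensities, peaks.widths):
        w = max(width, min_width)
        if lineshape == "lorentzian":
            hw = 0.5 * w
            out += inten * hw**2 / ((grid - pos) ** 2 + hw**2)
        elif lineshape == "gaussian":
            sigma = w / 2.3548  # FWHM -> sigma
            out += inten * np.exp(-0.5 * ((grid - pos) / sigma) ** 2)
        else:
            raise ValueError(f"unknown lineshape {lineshape!r}")
    return out


def vectorize_h1(trace_or_peaks, config: CodecConfig | None = None) -> SpectrumVector:
    """¹H intensity vector of length 10,000 over −2 to 10 ppm, scaled to [0, 1].

    Accepts either a :class:`PeakList1D` (rendered as a sum of Lorentzian
    lines) or a continuous trace as an ``(axis, values)`` pair of arrays.
    """
    cfg = config or CodecConfig()
    lo, hi = cfg.h1_range
    grid = np.linspace(lo, hi, cfg.h1_len)
    if isinstance(trace_or_peaks, PeakList1D):
        if trace_or_peaks.modality != "h1":
            raise ValueError(f"expected h1 peak list, got {trace_or_peaks.modality}")
        raw = _render_peaks_1d(grid, trace_or_peaks, cfg.h1_lineshape)
    else:
        axis, values = trace_or_peaks
        axis = np.asarray(axis, dtype=float)
        values = np.asarray(values, dtype=float)
        order = np.argsort(axis)
        raw = np.interp(grid, axis[order], values[order], left=0.0, right=0.0)
    return SpectrumVector("h1", minmax01(raw), lo, hi, "ppm")


def render_ir(trace_or_peaks, config: CodecConfig | None = None) -> np.ndarray:
    """Raw transmittance on the IR grid, before min-max scaling.

    Regions with no measurement are filled with baseline transmittance 1.0
    (no absorption). Peak-list input is interpreted as absorption bands
    subtracted from the unit baseline.
    """
    cfg = config or CodecConfig()
    lo, _ = cfg.ir_range
    grid = lo + IR_STEP * np.arange(cfg.ir_len)
    if isinstance(trace_or_peaks, PeakList1D):
        if trace_or_peaks.modality != "ir":
            raise ValueError(f"expected ir peak list, got {trace_or_peaks.modality}")
        absorption = _render_peaks_1d(grid, trace_or_peaks, "gaussian")
        return np.clip(1.0 - absorption, 0.0, 1.0)
    axis, values = trace_or_peaks
    axis = np.asarray(axis, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(axis) == 0:
        return np.ones(cfg.ir_len)
    order = np.argsort(axis)
    return np.interp(grid, axis[order], values[order], left=1.0, right=1.0)


def vectorize_ir(trace_or_peaks, config: CodecConfig | None = None) -> SpectrumVector:
    """IR transmittance vector of length 1600 over 600–3800 cm⁻¹, in [0, 1]."""
    cfg = config or CodecConfig()
    raw = render_ir(trace_or_peaks, cfg)
    return SpectrumVector("ir", minmax01(raw), cfg.ir_range[0], cfg.ir_range[1], "cm-1")


def rasterize_hsqc(
    peaks: list[HSQCPeak],
    augment: AugmentationConfig | None = None,
    config: CodecConfig | None = None,
) -> SpectrumVector:
    """Render C–H correlation peaks onto a 512 × 512 grid.

    Rows span the ¹³C axis (0–300 ppm), columns the ¹H axis (−2–10 ppm).
    Each peak becomes a 2-D Gaussian at its (optionally jittered) centroid
    with per-axis sigma = (max − min)/4, floored at one cell. Peaks falling
    entirely outside the window are dropped. The grid is max-normalised.
    """
    cfg = config or CodecConfig()
    aug = augment or AugmentationConfig.identity()
    n_c, n_h = cfg.hsqc_shape
    c_lo, c_hi = cfg.c13_range
    h_lo, h_hi = cfg.h1_range
    c_cell = (c_hi - c_lo) / n_c
    h_cell = (h_hi - h_lo) / n_h
    grid = np.zeros((n_c, n_h))
    rng = np.random.default_rng(aug.seed)
    c_axis = c_lo + (np.arange(n_c) + 0.5) * c_cell
    h_axis = h_lo + (np.arange(n_h) + 0.5) * h_cell
    for pk in peaks:
        cc, hc = pk.c_centroid, pk.h_centroid
        if aug.position_jitter > 0:
            cc += rng.normal(0.0, aug.position_jitter)
            hc += rng.normal(0.0, aug.position_jitter)
        if not (c_lo <= cc <= c_hi and h_lo <= hc <= h_hi):
            logger.warning("dropping HSQC peak outside window at (%.1f, %.2f)", cc, hc)
            continue
        sig_c = max((pk.c_max - pk.c_min) / 4.0 * aug.width_broadening, c_cell)
        sig_h = max((pk.h_max - pk.h_min) / 4.0 * aug.width_broadening, h_cell)
        gc = np.exp(-0.5 * ((c_axis - cc) / sig_c) ** 2)
        gh = np.exp(-0.5 * ((h_axis - hc) / sig_h) ** 2)
        grid += np.outer(gc, gh)
    if aug.noise_scale > 0 and grid.max() > 0:
        grid = grid + rng.normal(0.0, aug.noise_scale * grid.max(), grid.shape)
        grid = np.clip(grid, 0.0, None)
    peak_max = grid.max()
    if peak_max > 0:
        grid = grid / peak_max
    return SpectrumVector("hsqc", grid, c_lo, c_hi, "ppm")


def resample_linear(values: np.ndarray, target_len: int) -> np.ndarray:
    """Resample a uniform sequence to `target_len` by linear interpolation.

    Endpoints are preserved exactly (used to reduce 32,768-point instrument
    traces to the model's 10,000-point grid).
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or len(values) < 2:
        raise ValueError("input must be a 1-D sequence of length >= 2")
    if target_len < 2:
        raise ValueError("target_len must be >= 2")
    src = np.linspace(0.0, 1.0, len(values))
    dst = np.linspace(0.0, 1.0, target_len)
    out = np.interp(dst, src, values)
    out[0], out[-1] = values[0], values[-1]
    return out


def augment_h1(vector_or_peaks, config: AugmentationConfig):
    """Apply the ¹H augmentation suite; returns the same kind as the input.

    Peak-list input: position jitter and width broadening.
    Vector input: additive noise and slow sinusoidal baseline drift,
    re-scaled to [0, 1].
    Deterministic given ``config.seed``; all scales 0 is the identity.
    """
    rng = np.random.default_rng(config.seed)
    if isinstance(vector_or_peaks, PeakList1D):
        pk = vector_or_peaks
        positions = pk.positions.copy()
        if config.position_jitter > 0:
            positions = positions + rng.normal(0.0, config.position_jitter, len(pk))
        widths = pk.widths * config.width_broadening
        return PeakList1D(pk.modality, positions, pk.intensities.copy(), widths)
    vec = vector_or_peaks
    values = vec.values.copy()
    scale = values.max() if values.max() > 0 else 1.0
    changed = False
    if config.noise_scale > 0:
        values = values + rng.normal(0.0, config.noise_scale * scale, values.shape)
        changed = True
    if config.baseline_drift > 0:
        n = len(values)
        phase = rng.uniform(0.0, 2 * np.pi)
        values = values + config.baseline_drift * scale * np.sin(
            2 * np.pi * np.arange(n) / n + phase
        )
        changed = True
    if changed:
        values = minmax01(np.clip(values, 0.0, None))
    return SpectrumVector(vec.modality, values, vec.axis_lo, vec.axis_hi, vec.units)
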