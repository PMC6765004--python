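"""Beam and image quality metrics: lobe widths/levels, contrast, CNR.

All profile metrics operate on a `BeamProfile`, a lateral cut through a
field or image at a fixed depth, normalized so the peak is 0 dB.  Contrast
and CNR are amplitude-ratio statistics,

    contrast = 20 log10(mu_i / mu_o)
    CNR      = 20 log10((mu_o - mu_i) / sqrt(sigma_o^2 + sigma_i^2))

with the means/standard deviations taken over circular regions of interest
on the *linear* (pre-log-compression) envelope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import argrelextrema, find_peaks

__all__ = [
    "BeamProfile",
    "LobeReport",
    "Circle",
    "ROIStats",
    "lobe_width",
    "find_sidelobes",
    "level_at",
    "roi_stats",
    "contrast",
    "cnr",
    "envelope_snr",
    "load_profile",
]

_DB_FLOOR = -300.0


def _to_db(amplitude: np.ndarray, ref: float | None = None) -> np.ndarray:
    a = np.asarray(amplitude, dtype=float)
    if ref is None:
        ref = a.max()
    if ref <= 0:
        raise ValueError("cannot normalize: non-positive reference amplitude")
    with np.errstate(divide="ignore"):
        db = 20.0 * np.log10(a / ref)
    return np.maximum(db, _DB_FLOOR)


@dataclass(frozen=True, eq=False)
class BeamProfile:
    """Normalized lateral profile at a fixed depth: level in dB, peak at 0."""

    x: np.ndarray       # mm, strictly increasing
    level: np.ndarray   # dB, max = 0
    depth: float        # mm

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        lv = np.asarray(self.level, dtype=float)
        if x.ndim != 1 or x.shape != lv.shape:
            raise ValueError("x and level must be 1-D of equal length")
        if np.any(np.diff(x) <= 0):
            raise ValueError("x must be strictly increasing")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "level", lv)

    @classmethod
    def from_amplitude(cls, x: np.ndarray, amplitude: np.ndarray,
                       depth: float) -> "BeamProfile":
        return cls(x=np.asarray(x, float), level=_to_db(amplitude),
                   depth=float(depth))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"x_mm": self.x, "amplitude_dB": self.level}).to_csv(
            path, index=False)

    def mirrored(self) -> "BeamProfile":
        return BeamProfile(x=-self.x[::-1], level=self.level[::-1],
                           depth=self.depth)


def load_profile(path: str | Path, depth: float = 0.0) -> BeamProfile:
    df = pd.read_csv(path)
    return BeamProfile(x=df["x_mm"].to_numpy(),
                       level=df["amplitude_dB"].to_numpy(), depth=depth)


@dataclass(frozen=True)
class LobeReport:
    """Main-lobe and side-lobe summary of a profile."""

    main_peak_x: float
    width_at_level: float          # mm, full width at `width_level`
    width_level: float             # dB
    sidelobe_positions: tuple[float, ...]
    sidelobe_levels: tuple[float, ...]
    first_order_positions: tuple[float, ...]   # (left, right) when both exist
    first_order_levels: tuple[float, ...]
    mean_first_order_level: float  # arithmetic mean of the two dB levels


def level_at(profile: BeamProfile, x: float) -> float:
    """Linearly interpolated profile level (dB) at lateral position `x`."""
    if not (profile.x[0] <= x <= profile.x[-1]):
        raise ValueError(f"x={x} outside profile support")
    return float(np.interp(x, profile.x, profile.level))


def _parabolic_refine(x: np.ndarray, y: np.ndarray, i: int) -> tuple[float, float]:
    """Refine a discrete extremum through the parabola over 3 points."""
    if i == 0 or i == y.size - 1:
        return float(x[i]), float(y[i])
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(x[i]), float(y[i])
    d = 0.5 * (y0 - y2) / denom
    d = float(np.clip(d, -1, 1))
    xr = x[i] + d * (x[i + 1] - x[i - 1]) / 2.0
    yr = y1 - 0.25 * (y0 - y2) * d
    return float(xr), float(yr)


def lobe_width(profile: BeamProfile, level: float = -3.0) -> float:
    """Full width of the main lobe at `level` dB (linearly interpolated).

    Walks outward from the global peak to the nearest crossing of `level`
    on each side.
    """
    if level >= 0:
        raise ValueError("level must be negative (dB below the peak)")
    x, lv = profile.x, profile.level
    i_pk = int(np.argmax(lv))
    thr = lv[i_pk] + level

    def _cross(direction: int) -> float:
        i = i_pk
        while 0 <= i + direction < lv.size:
            j = i + direction
            if lv[j] <= thr:
                # linear interpolation between i and j
                frac = (lv[i] - thr) / (lv[i] - lv[j])
                return float(x[i] + frac * (x[j] - x[i]))
            i = j
        raise ValueError(f"profile never crosses {level} dB on one side")

    return _cross(+1) - _cross(-1)


def find_sidelobes(profile: BeamProfile, width_level: float = -3.0,
                   prominence: float = 0.5) -> LobeReport:
    """Locate side lobes: local maxima outside the main lobe.

    The main lobe is bounded by the first local minima flanking the global
    peak; the first-order side lobes are the nearest local maxima beyond
    those bounds on each side.  Peak positions/levels are refined with a
    3-point parabola.  A monotone profile yields an empty side-lobe list.
    """
    x, lv = profile.x, profile.level
    i_pk = int(np.argmax(lv))
    main_x, _ = _parabolic_refine(x, lv, i_pk)

    minima = argrelextrema(lv, np.less_equal, order=1)[0]
    left_min = minima[minima < i_pk]
    right_min = minima[minima > i_pk]
    lo = int(left_min.max()) if left_min.size else None
    hi = int(right_min.min()) if right_min.size else None

    positions: list[float] = []
    levels: list[float] = []
    first_left: tuple[float, float] | None = None
    first_right: tuple[float, float] | None = None

    if lo is not None and lo > 0:
        pk, _ = find_peaks(lv[: lo + 1], prominence=prominence)
        for i in pk[::-1]:
            xr, yr = _parabolic_refine(x, lv, int(i))
            positions.append(xr)
            levels.append(yr)
            if first_left is None:
                first_left = (xr, yr)
    if hi is not None and hi < lv.size - 1:
        pk, _ = find_peaks(lv[hi:], prominence=prominence)
        for i in pk + hi:
            xr, yr = _parabolic_refine(x, lv, int(i))
            positions.append(xr)
            levels.append(yr)
            if first_right is None:
                first_right = (xr, yr)

    first_pos: list[float] = []
    first_lvl: list[float] = []
    for item in (first_left, first_right):
        if item is not None:
            first_pos.append(item[0])
            first_lvl.append(item[1])
    mean_first = float(np.mean(first_lvl)) if first_lvl else math.nan

    order = np.argsort(positions)
    return LobeReport(
        main_peak_x=main_x,
        width_at_level=lobe_width(profile, width_level),
        width_level=width_level,
        sidelobe_positions=tuple(np.asarray(positions)[order]),
        sidelobe_levels=tuple(np.asarray(levels)[order]),
        first_order_positions=tuple(first_pos),
        first_order_levels=tuple(first_lvl),
        mean_first_order_level=mean_first,
    )


@dataclass(frozen=True)
class Circle:
    """Circular region of interest in the image plane (mm)."""

    x: float
    z: float
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")


@dataclass(frozen=True)
class ROIStats:
    """Mean/std of the linear envelope inside a circular ROI."""

    mean: float
    std: float
    n_pixels: int


def _roi_mask(image, roi: Circle) -> np.ndarray:
    xx, zz = np.meshgrid(image.x, image.z)
    mask = (xx - roi.x) ** 2 + (zz - roi.z) ** 2 <= roi.radius**2
    mask &= np.isfinite(image.envelope) & (image.envelope > 0)
    return mask


def roi_stats(image, roi: Circle) -> ROIStats:
    """Envelope statistics inside `roi`; `image` needs .envelope/.x/.z."""
    mask = _roi_mask(image, roi)
    vals = np.asarray(image.envelope)[mask]
    if vals.size == 0:
        raise ValueError("ROI contains no valid image pixels")
    return ROIStats(mean=float(vals.mean()), std=float(vals.std()),
                    n_pixels=int(vals.size))


def contrast(image, roi_in: Circle, roi_out: Circle) -> float:
    """Lesion contrast 20 log10(mu_in / mu_out) in dB (negative = darker)."""
    mu_i = roi_stats(image, roi_in).mean
    mu_o = roi_stats(image, roi_out).mean
    if mu_o == 0:
        raise ValueError("background mean is zero; contrast undefined")
    if mu_i == 0:
        return -math.inf
    return 20.0 * math.log10(mu_i / mu_o)


def cnr(image, roi_in: Circle, roi_out: Circle) -> float:
    """Contrast-to-noise ratio 20 log10((mu_o - mu_i)/sqrt(s_o^2 + s_i^2)).

    For an anechoic lesion mu_o > mu_i and the value is the detectability in
    dB.  If mu_o <= mu_i the log argument is not positive; the function then
    returns the sign-flipped magnitude ratio as an explicit diagnostic
    (and -inf when the means are exactly equal).
    """
    s_i = roi_stats(image, roi_in)
    s_o = roi_stats(image, roi_out)
    noise = math.hypot(s_i.std, s_o.std)
    if noise == 0:
        raise ValueError("both ROIs have zero variance; CNR undefined")
    diff = s_o.mean - s_i.mean
    if diff == 0:
        return -math.inf
    value = 20.0 * math.log10(abs(diff) / noise)
    return value if diff > 0 else -value


def envelope_snr(image, roi: Circle) -> float:
    """Envelope SNR mu/sigma in an ROI (~1.91 for fully developed speckle)."""
    s = roi_stats(image, roi)
    if s.std == 0:
        raise ValueError("zero variance in ROI")
    return s.mean / s.std
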