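"""Per-element delay/apodization maps: single focus, two foci, Hamming, interlaced.

A transmit scheme is the pair (delay map, apodization map) — the only
degrees of freedom a conventional scanner exposes on transmit.  The
side-lobe-reduction scheme interlaces two designs on one aperture:

    WF = WF_single_focus[odd elements] + c * WF_two_foci(dx)[even elements]

Odd/even counts ordinal position along the array in 1-based counting, with
element 1 at the most negative lateral position.  The two-foci waveform is
designed with the pseudo-inverse method: solve a monochromatic propagation
matrix (foci x elements) for complex element weights that produce equal
pressure at both foci, then re-encode magnitude as apodization and phase as
a delay (modulo one carrier period, resolved toward the smooth geometric
focusing law).

Phase-reference convention: the two-foci delays are referenced to the
focal arrival clock t_ref = max_i R_i(foci centroid)/c — the same instant
at which the single-focus law (min delay = 0 at the edge elements)
delivers its focal peak.  Interlacing therefore combines the two waveforms
carrier-phase-coherently without any cross-normalization, which is what
makes a purely real amplitude coefficient c sufficient for destructive
interference at the side lobes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .array_model import Medium, TransducerArray

__all__ = [
    "TransmitScheme",
    "USLRParams",
    "focus_delays",
    "two_foci_scheme",
    "multi_foci_scheme",
    "hamming_scheme",
    "interlace",
    "uslr_scheme",
    "odd_element_mask",
    "restrict",
    "odd_elements",
    "even_elements",
    "load_scheme",
]


@dataclass(frozen=True, eq=False)
class TransmitScheme:
    """Per-element transmit delays (µs, >= 0) and apodization amplitudes."""

    delays: np.ndarray
    apodization: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        d = np.asarray(self.delays, dtype=float)
        a = np.asarray(self.apodization, dtype=float)
        if d.shape != a.shape or d.ndim != 1:
            raise ValueError("delays and apodization must be 1-D with equal length")
        if not (np.all(np.isfinite(d)) and np.all(np.isfinite(a))):
            raise ValueError("delays/apodization must be finite")
        if np.any(d < 0) or np.any(a < 0):
            raise ValueError("delays and apodization must be non-negative")
        object.__setattr__(self, "delays", d)
        object.__setattr__(self, "apodization", a)

    @property
    def n_elements(self) -> int:
        return self.delays.size

    @property
    def n_active(self) -> int:
        """Number of elements with nonzero apodization."""
        return int(np.count_nonzero(self.apodization))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "element_index": np.arange(1, self.n_elements + 1),
                "delay_us": self.delays,
                "apodization": self.apodization,
            }
        ).to_csv(path, index=False)


def load_scheme(path: str | Path, label: str = "") -> TransmitScheme:
    df = pd.read_csv(path)
    return TransmitScheme(
        delays=df["delay_us"].to_numpy(),
        apodization=df["apodization"].to_numpy(),
        label=label or str(path),
    )


@dataclass(frozen=True)
class USLRParams:
    """Interlacing parameters: amplitude coefficient c and foci separation (mm)."""

    c: float
    delta_x: float

    def __post_init__(self) -> None:
        if self.c < 0:
            raise ValueError("c must be >= 0")
        if self.delta_x <= 0:
            raise ValueError("delta_x must be positive")


def _element_focus_distances(
    array: TransducerArray, focus: tuple[float, float]
) -> np.ndarray:
    fx, fz = focus
    if fz <= 0:
        raise ValueError("focus depth must be positive")
    return np.hypot(fx - array.element_x, fz)


def focus_delays(
    array: TransducerArray,
    focus: tuple[float, float],
    medium: Medium | None = None,
    label: str = "single-focus",
) -> TransmitScheme:
    """Single-focus delay law with rectangular apodization.

    delays[i] = (max_j R_j - R_i) / c so that all pulses arrive at the focus
    simultaneously (at t = max_j R_j / c) and the minimum delay is exactly 0.
    """
    medium = medium or Medium()
    r = _element_focus_distances(array, focus)
    delays = (r.max() - r) / medium.c
    return TransmitScheme(delays=delays, apodization=np.ones(array.n_elements),
                          label=label)


def multi_foci_scheme(
    array: TransducerArray,
    foci: np.ndarray,
    medium: Medium | None = None,
    label: str = "multi-foci",
) -> TransmitScheme:
    """Pseudo-inverse design of a scheme focusing at several points at once.

    Builds the monochromatic propagation matrix H[k, i] =
    exp(-j 2 pi f0 R_ki / c) / R_ki at the carrier frequency and solves
    w = pinv(H) @ 1 (equal unit pressure requested at every focus).  The
    complex weights are re-encoded for delay/apodization hardware:
    apodization = |w| / max|w|, and arg(w) becomes a delay referenced to
    t_ref, the focal arrival time of the matching single-focus law at the
    foci centroid.  The carrier-period ambiguity of the phase is resolved
    toward the smooth geometric focusing law at the centroid, so each
    element's delay differs from that law by at most half a period: the
    broadband pulses stay time-aligned while the carrier phase (including
    the pi flips of the two-foci fringe pattern, encoded as half-period
    offsets) stays locked to the common focal clock.
    """
    medium = medium or Medium()
    foci = np.atleast_2d(np.asarray(foci, dtype=float))
    if foci.shape[1] != 2 or np.any(foci[:, 1] <= 0):
        raise ValueError("foci must be (n, 2) points with positive depth")
    f0 = array.center_frequency
    omega = 2 * np.pi * f0          # rad/µs
    period = 1.0 / f0               # µs
    r = np.hypot(foci[:, :1] - array.element_x[None, :], foci[:, 1:2])
    h = np.exp(-1j * omega * r / medium.c) / r
    w = np.linalg.pinv(h) @ np.ones(foci.shape[0])
    apod = np.abs(w)
    apod = apod / apod.max()
    centroid = foci.mean(axis=0)
    r_centroid = _element_focus_distances(array, (centroid[0], centroid[1]))
    t_ref = r_centroid.max() / medium.c
    d_geo = (r_centroid.max() - r_centroid) / medium.c
    d_raw = t_ref - np.angle(w) / omega
    delays = d_raw + period * np.round((d_geo - d_raw) / period)
    if delays.min() < 0:  # keep delays >= 0; a full-period shift is phase-free
        delays = delays + period
    return TransmitScheme(delays=delays, apodization=apod, label=label)


def two_foci_scheme(
    array: TransducerArray,
    depth: float,
    delta_x: float,
    medium: Medium | None = None,
) -> TransmitScheme:
    """Two symmetric foci at (+/- delta_x / 2, depth), pseudo-inverse design."""
    if depth <= 0:
        raise ValueError("depth must be positive")
    if delta_x < 0:
        raise ValueError("delta_x must be >= 0")
    foci = np.array([[-delta_x / 2.0, depth], [delta_x / 2.0, depth]])
    return multi_foci_scheme(array, foci, medium,
                             label=f"two-foci(dx={delta_x:g}mm)")


def hamming_scheme(
    array: TransducerArray,
    focus: tuple[float, float],
    medium: Medium | None = None,
) -> TransmitScheme:
    """Single-focus delays with a Hamming apodization over element index."""
    base = focus_delays(array, focus, medium, label="hamming")
    n = array.n_elements
    idx = np.arange(n)
    apod = 0.54 - 0.46 * np.cos(2 * np.pi * idx / (n - 1))
    return replace(base, apodization=apod)


def odd_element_mask(n_elements: int) -> np.ndarray:
    """True for odd elements in 1-based ordinal counting (1st, 3rd, ...)."""
    return (np.arange(n_elements) % 2) == 0


def interlace(
    single: TransmitScheme, two_foci: TransmitScheme, c: float
) -> TransmitScheme:
    """Interlace two schemes: odd elements from `single`, even from c * `two_foci`.

    Delay maps are taken verbatim from each source scheme — no
    re-normalization across the interlace, preserving their mutual phase.
    """
    if single.n_elements != two_foci.n_elements:
        raise ValueError("schemes must be defined on the same array")
    if c < 0:
        raise ValueError("c must be >= 0")
    odd = odd_element_mask(single.n_elements)
    delays = np.where(odd, single.delays, two_foci.delays)
    apod = np.where(odd, single.apodization, c * two_foci.apodization)
    return TransmitScheme(delays=delays, apodization=apod,
                          label=f"interlaced(c={c:g})")


def uslr_scheme(
    array: TransducerArray,
    depth: float,
    params: USLRParams,
    medium: Medium | None = None,
) -> TransmitScheme:
    """Optimizable side-lobe-reduction scheme at an on-axis focal depth."""
    single = focus_delays(array, (0.0, depth), medium)
    two = two_foci_scheme(array, depth, params.delta_x, medium)
    out = interlace(single, two, params.c)
    return replace(out, label=f"uslr(c={params.c:g},dx={params.delta_x:g}mm)")


def restrict(scheme: TransmitScheme, keep: np.ndarray) -> TransmitScheme:
    """Zero the apodization of every element where `keep` is False."""
    keep = np.asarray(keep, dtype=bool)
    if keep.shape != scheme.apodization.shape:
        raise ValueError("mask length must match scheme length")
    return replace(scheme, apodization=np.where(keep, scheme.apodization, 0.0))


def odd_elements(scheme: TransmitScheme) -> TransmitScheme:
    """Scheme transmitted on the odd elements only (1-based counting)."""
    out = restrict(scheme, odd_element_mask(scheme.n_elements))
    return replace(out, label=scheme.label + "[odd]")


def even_elements(scheme: TransmitScheme) -> TransmitScheme:
    out = restrict(scheme, ~odd_element_mask(scheme.n_elements))
    return replace(out, label=scheme.label + "[even]")
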