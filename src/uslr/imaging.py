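"""Sector imaging: channel-data simulation, delay-and-sum, B-mode rendering.

Echo simulation uses a first-order (single-scattering) Born model with
point elements: for scatterer k and receive element j,

    rx_j(t) = sum_k s_k / R_kj * a_k(t - R_kj / c),
    a_k(t)  = sum_i apod_i / R_ik * pulse(t - delay_i - R_ik / c),

i.e. the transmit field is evaluated at each scatterer and re-radiated
spherically to the receivers.  Receive-element directivity and transducer
bandwidth are deliberately ignored; side-lobe structure is delay-driven.

Beamforming is conventional delay-and-sum with dynamic receive focusing
along each steered scanline, full-aperture rectangular receive
apodization, envelope detection per scanline, polar-to-Cartesian scan
conversion (bilinear) and log compression normalized to a 0 dB peak.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
from scipy.ndimage import map_coordinates
from scipy.signal import hilbert

from .array_model import Medium, Pulse, TransducerArray, emitted_pulse
from .field_sim import lateral_profile_of_scheme
from .metrics import BeamProfile, find_sidelobes
from .phantoms import ScattererPhantom
from .waveform_design import (
    TransmitScheme,
    USLRParams,
    focus_delays,
    hamming_scheme,
    interlace,
    multi_foci_scheme,
    odd_elements,
)

__all__ = [
    "SectorGeometry",
    "ChannelData",
    "BModeImage",
    "steer_scheme",
    "steered_scheme",
    "simulate_channel_data",
    "sweep_sector",
    "das_beamform",
    "image_lateral_profile",
    "two_way_profile",
    "grating_lobe_analysis",
    "GratingLobeReport",
    "save_image",
    "load_image",
]


@dataclass(frozen=True)
class SectorGeometry:
    """Steered-sector acquisition geometry."""

    n_angles: int = 256
    field_of_view: float = 18.0      # deg, total angular span
    focal_depth: float = 60.0        # mm
    depth_range: tuple[float, float] = (40.0, 80.0)

    def __post_init__(self) -> None:
        if self.n_angles < 1:
            raise ValueError("n_angles must be >= 1")
        if self.field_of_view <= 0:
            raise ValueError("field_of_view must be positive")
        if not (0 < self.depth_range[0] < self.depth_range[1]):
            raise ValueError("depth_range must be increasing and positive")

    @property
    def angles(self) -> np.ndarray:
        """Steering angles (deg), uniformly spanning the field of view."""
        if self.n_angles == 1:
            return np.zeros(1)
        half = self.field_of_view / 2.0
        return np.linspace(-half, half, self.n_angles)


@dataclass(frozen=True, eq=False)
class ChannelData:
    """Received RF traces, one per element, for a single transmission."""

    samples: np.ndarray       # (n_elements, n_times)
    sampling_rate: float      # MHz
    t0: float                 # µs, time of the first sample
    angle: float = 0.0        # deg, steering angle of the transmission

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=float)
        if s.ndim != 2:
            raise ValueError("samples must be (n_elements, n_times)")
        if not np.all(np.isfinite(s)):
            raise ValueError("samples must be finite")
        object.__setattr__(self, "samples", s)


@dataclass(frozen=True, eq=False)
class BModeImage:
    """Scan-converted image holding the linear envelope and display params.

    `pixels` is the log-compressed display: 20 log10(envelope / max),
    clipped at -dynamic_range; pixels outside the imaged sector (zero
    envelope) sit at the clip floor.  Metrics use `envelope` directly.
    """

    envelope: np.ndarray      # (nz, nx), linear, >= 0
    x: np.ndarray             # mm
    z: np.ndarray             # mm
    dynamic_range: float = 50.0

    def __post_init__(self) -> None:
        env = np.asarray(self.envelope, dtype=float)
        if env.shape != (np.asarray(self.z).size, np.asarray(self.x).size):
            raise ValueError("envelope shape must be (nz, nx)")
        object.__setattr__(self, "envelope", env)
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        object.__setattr__(self, "z", np.asarray(self.z, dtype=float))

    @property
    def pixels(self) -> np.ndarray:
        peak = self.envelope.max()
        if peak <= 0:
            raise ValueError("empty image")
        with np.errstate(divide="ignore"):
            db = 20.0 * np.log10(self.envelope / peak)
        return np.maximum(db, -self.dynamic_range)


def steered_scheme(
    array: TransducerArray,
    depth: float,
    angle: float,
    medium: Medium | None = None,
    kind: str = "single",
    params: USLRParams | None = None,
) -> TransmitScheme:
    """Transmit scheme focused at range `depth` along a steered beam axis.

    The focal point is (depth sin(angle), depth cos(angle)).  For the
    interlaced kind the two foci are offset by +/- delta_x/2 along the
    direction perpendicular to the beam axis, at the same range.
    """
    if abs(angle) > 45.0:
        raise ValueError("steering limited to +/-45 deg")
    medium = medium or Medium()
    th = np.deg2rad(angle)
    fx, fz = depth * np.sin(th), depth * np.cos(th)
    if kind == "single":
        return focus_delays(array, (fx, fz), medium)
    if kind == "hamming":
        return hamming_scheme(array, (fx, fz), medium)
    if kind == "uslr":
        if params is None:
            raise ValueError("kind='uslr' requires params")
        single = focus_delays(array, (fx, fz), medium)
        perp = np.array([np.cos(th), -np.sin(th)])
        offset = 0.5 * params.delta_x * perp
        foci = np.array([[fx, fz] - offset, [fx, fz] + offset])
        two = multi_foci_scheme(array, foci, medium)
        return interlace(single, two, params.c)
    raise ValueError(f"unknown scheme kind {kind!r}")


# spec-facing alias
steer_scheme = steered_scheme


def simulate_channel_data(
    array: TransducerArray,
    scheme: TransmitScheme,
    phantom: ScattererPhantom,
    pulse: Pulse,
    medium: Medium | None = None,
    fs: float | None = None,
    angle: float = 0.0,
    pad: float = 0.2,
    chunk: int = 256,
) -> ChannelData:
    """Born single-scattering echo traces for one transmission."""
    medium = medium or Medium()
    if fs is None:
        fs = 8.0 * array.center_frequency
    ex = array.element_x
    n_el = ex.size
    if phantom.n_scatterers == 0:
        t0 = 0.0
        return ChannelData(samples=np.zeros((n_el, 16)), sampling_rate=fs,
                           t0=t0, angle=angle)

    pos = phantom.positions
    refl = phantom.reflectivities
    r = np.hypot(pos[:, 0:1] - ex[None, :], pos[:, 1:2])     # (K, n_el)
    if np.any(r < 1e-6):
        raise ValueError("scatterer coincides with an element")
    c = medium.c
    atten = None
    if medium.attenuation > 0:
        atten = 10.0 ** (
            -medium.attenuation * array.center_frequency * (r / 10.0) / 20.0
        )

    tau_tx = scheme.delays[None, :] + r / c
    amp_tx = scheme.apodization[None, :] / r
    if atten is not None:
        amp_tx = amp_tx * atten

    # per-scatterer transmit-arrival window
    w_start = tau_tx.min(axis=1) - pad
    span = float((tau_tx.max(axis=1) - tau_tx.min(axis=1)).max())
    n_w = int(np.ceil((span + pulse.duration + 2 * pad) * fs)) + 2
    w_t = np.arange(n_w) / fs

    # global receive time axis
    arr_start = w_start[:, None] + r / c                      # (K, n_el)
    t0 = float(arr_start.min())
    n_t = int(np.ceil((arr_start.max() + n_w / fs - t0) * fs)) + 2
    traces = np.zeros(n_el * n_t)

    amp_rx = refl[:, None] / r
    if atten is not None:
        amp_rx = amp_rx * atten
    el_idx = np.arange(n_el)

    for k0 in range(0, pos.shape[0], chunk):
        k1 = min(k0 + chunk, pos.shape[0])
        # stage 1: transmit field time series at each scatterer
        arg = (w_start[k0:k1, None, None] + w_t[None, None, :]
               - tau_tx[k0:k1, :, None])
        a = (amp_tx[k0:k1, :, None] * pulse(arg)).sum(axis=1)   # (k, n_w)
        # stage 2: splat each window into the receive traces with a
        # linearly interpolated fractional delay
        f_idx = (arr_start[k0:k1] - t0) * fs                    # (k, n_el)
        n0 = np.floor(f_idx).astype(np.int64)
        frac = f_idx - n0
        base = (el_idx[None, :, None] * n_t + n0[:, :, None]
                + np.arange(n_w)[None, None, :])                # (k, n_el, n_w)
        w = a[:, None, :] * amp_rx[k0:k1, :, None]
        w0 = (w * (1.0 - frac[:, :, None])).ravel()
        w1 = (w * frac[:, :, None]).ravel()
        flat = base.ravel()
        traces += np.bincount(flat, weights=w0, minlength=traces.size)
        traces += np.bincount(flat + 1, weights=w1, minlength=traces.size)

    return ChannelData(samples=traces.reshape(n_el, n_t), sampling_rate=fs,
                       t0=t0, angle=angle)


def sweep_sector(
    array: TransducerArray,
    phantom: ScattererPhantom,
    geometry: SectorGeometry,
    medium: Medium | None = None,
    pulse: Pulse | None = None,
    kind: str = "single",
    params: USLRParams | None = None,
    fs: float | None = None,
) -> list[ChannelData]:
    """Acquire one steered transmission per sector angle."""
    medium = medium or Medium()
    pulse = pulse or emitted_pulse(array.center_frequency)
    out = []
    for angle in geometry.angles:
        scheme = steered_scheme(array, geometry.focal_depth, float(angle),
                                medium, kind=kind, params=params)
        out.append(simulate_channel_data(array, scheme, phantom, pulse,
                                         medium, fs=fs, angle=float(angle)))
    return out


def _transmit_clock(array: TransducerArray, geometry: SectorGeometry,
                    angle: float, medium: Medium) -> float:
    """Focal arrival time of the steered single-focus law (µs)."""
    th = np.deg2rad(angle)
    fx, fz = geometry.focal_depth * np.sin(th), geometry.focal_depth * np.cos(th)
    return float(np.hypot(fx - array.element_x, fz).max() / medium.c)


def das_beamform(
    channel_sets: list[ChannelData],
    array: TransducerArray,
    geometry: SectorGeometry,
    medium: Medium | None = None,
    pulse: Pulse | None = None,
    pixel_size: float = 0.05,
    dynamic_range: float = 50.0,
) -> BModeImage:
    """Delay-and-sum with dynamic receive focusing; scan-converted B-mode.

    The transmit wavefront is assumed to pass range r on the beam axis at
    t_tx(r) = t_focal + (r - r_focal)/c, the standard virtual-clock model
    for a focused transmission.  Range sampling is c/(2 fs_img) with
    fs_img = 4 f0.  When the emitted `pulse` is given, its envelope-peak
    lag is compensated so echoes map to the scatterer range rather than
    `lag/2` beyond it (a band-limited pulse peaks well after its onset).
    """
    medium = medium or Medium()
    lag = 0.0
    if pulse is not None:
        env = np.abs(hilbert(pulse.samples))
        lag = float(np.argmax(env) / pulse.sampling_rate)
    if len(channel_sets) != geometry.n_angles:
        raise ValueError("need one ChannelData per sector angle")
    order = np.argsort([cd.angle for cd in channel_sets])
    channel_sets = [channel_sets[i] for i in order]
    angles = np.array([cd.angle for cd in channel_sets])

    c = medium.c
    fs_img = 4.0 * array.center_frequency
    dr = c / (2.0 * fs_img)
    r = np.arange(geometry.depth_range[0], geometry.depth_range[1], dr)
    ex = array.element_x

    env_polar = np.empty((angles.size, r.size))
    for ia, cd in enumerate(channel_sets):
        th = np.deg2rad(cd.angle)
        px = r * np.sin(th)
        pz = r * np.cos(th)
        t_focal = _transmit_clock(array, geometry, cd.angle, medium)
        t_tx = t_focal + (r - geometry.focal_depth) / c + lag
        r_rx = np.hypot(px[:, None] - ex[None, :], pz[:, None])  # (n_r, n_el)
        t = t_tx[:, None] + r_rx / c
        f_idx = (t - cd.t0) * cd.sampling_rate
        n_t = cd.samples.shape[1]
        i0 = np.clip(np.floor(f_idx).astype(np.int64), 0, n_t - 2)
        frac = np.clip(f_idx - i0, 0.0, 1.0)
        tr = cd.samples
        el = np.broadcast_to(np.arange(ex.size)[None, :], i0.shape)
        vals = tr[el, i0] * (1.0 - frac) + tr[el, i0 + 1] * frac
        # zero out samples requested beyond the recorded trace
        vals[(f_idx < 0) | (f_idx > n_t - 1)] = 0.0
        line = vals.sum(axis=1)
        env_polar[ia] = np.abs(hilbert(line))

    # scan conversion (bilinear) onto a Cartesian grid
    th_max = np.deg2rad(angles.max())
    x_max = r[-1] * np.sin(abs(th_max)) if angles.size > 1 else pixel_size
    x = np.arange(-x_max, x_max + pixel_size / 2, pixel_size)
    z = np.arange(r[0], r[-1] + pixel_size / 2, pixel_size)
    xx, zz = np.meshgrid(x, z)
    th_pix = np.rad2deg(np.arctan2(xx, zz))
    r_pix = np.hypot(xx, zz)
    if angles.size > 1:
        ai = (th_pix - angles[0]) / (angles[1] - angles[0])
    else:
        ai = np.zeros_like(th_pix)
    ri = (r_pix - r[0]) / dr
    env = map_coordinates(env_polar, [ai, ri], order=1, mode="constant",
                          cval=0.0)
    return BModeImage(envelope=env, x=x, z=z, dynamic_range=dynamic_range)


def image_lateral_profile(image: BModeImage, depth: float) -> BeamProfile:
    """Lateral dB cut through the image at `depth`, self-normalized."""
    if not (image.z[0] <= depth <= image.z[-1]):
        raise ValueError("depth outside image")
    iz = int(np.argmin(np.abs(image.z - depth)))
    row = image.envelope[iz]
    keep = row > 0
    return BeamProfile.from_amplitude(image.x[keep], row[keep],
                                      depth=float(image.z[iz]))


def two_way_profile(tx_profile: BeamProfile, rx_profile: BeamProfile
                    ) -> BeamProfile:
    """Pulse-echo profile: the product of transmit and receive patterns.

    In dB the profiles add; the result is renormalized to a 0 dB peak.
    """
    if tx_profile.x.shape != rx_profile.x.shape or not np.allclose(
            tx_profile.x, rx_profile.x):
        raise ValueError("profiles must share a common lateral axis")
    level = tx_profile.level + rx_profile.level
    return BeamProfile(x=tx_profile.x, level=level - level.max(),
                       depth=tx_profile.depth)


@dataclass(frozen=True)
class GratingLobeReport:
    """One-way and two-way grating-lobe levels of the interlaced transmit."""

    tx_level: float              # dB re main lobe (negative)
    rx_level: float              # full-aperture level at the grating position
    two_way_level: float         # dB re main lobe of the two-way profile
    tx_position: float           # mm
    two_way_position: float      # mm
    tx_suppression: float        # -tx_level (positive dB)
    two_way_suppression: float   # -two_way_level


def grating_lobe_analysis(
    array: TransducerArray,
    depth: float,
    medium: Medium | None = None,
    pulse: Pulse | None = None,
    half_span_deg: float = 48.0,
    step: float = 0.1,
    fs: float = 40.0,
    exclude_deg: float = 20.0,
) -> GratingLobeReport:
    """Grating lobes of the odd-element transmit vs full-aperture receive.

    Simulates (a) the odd-elements-only single-focus transmit profile over a
    wide lateral span (doubled effective pitch -> grating lobes appear off
    axis for the broadband pulse) and (b) the full-aperture one-way profile
    as the receive surrogate.  Grating peaks are searched beyond
    `exclude_deg` from the axis; the two-way profile is the dB sum.
    """
    medium = medium or Medium()
    pulse = pulse or emitted_pulse(array.center_frequency)
    span = depth * np.tan(np.deg2rad(half_span_deg))
    x = np.arange(-span, span + step / 2, step)
    single = focus_delays(array, (0.0, depth), medium)
    prof_tx = lateral_profile_of_scheme(array, odd_elements(single), pulse,
                                        depth, medium, x=x, fs=fs)
    prof_rx = lateral_profile_of_scheme(array, single, pulse, depth, medium,
                                        x=x, fs=fs)
    prof_2w = two_way_profile(prof_tx, prof_rx)

    far = np.abs(np.arctan2(x, depth)) > np.deg2rad(exclude_deg)
    if not np.any(far):
        raise ValueError("exclusion region covers the whole span")
    i_tx = np.flatnonzero(far)[np.argmax(prof_tx.level[far])]
    i_2w = np.flatnonzero(far)[np.argmax(prof_2w.level[far])]
    tx_level = float(prof_tx.level[i_tx])
    rx_level = float(prof_rx.level[i_tx])
    two_way_level = float(prof_2w.level[i_2w])
    return GratingLobeReport(
        tx_level=tx_level,
        rx_level=rx_level,
        two_way_level=two_way_level,
        tx_position=float(x[i_tx]),
        two_way_position=float(x[i_2w]),
        tx_suppression=-tx_level,
        two_way_suppression=-two_way_level,
    )


def save_image(image: BModeImage, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("envelope", data=image.envelope)
        f.create_dataset("x_mm", data=image.x)
        f.create_dataset("z_mm", data=image.z)
        f.attrs["dynamic_range"] = image.dynamic_range


def load_image(path: str | Path) -> BModeImage:
    with h5py.File(path, "r") as f:
        return BModeImage(envelope=f["envelope"][:], x=f["x_mm"][:],
                          z=f["z_mm"][:],
                          dynamic_range=float(f.attrs["dynamic_range"]))
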