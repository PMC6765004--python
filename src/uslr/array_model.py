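"""Transducer array, excitation pulse and propagation medium.

Units convention used throughout the package: lengths in **mm**, times in
**µs**, frequencies in **MHz**.  ``Medium.sound_speed`` is given in m/s (the
customary unit for tissue sound speed) and converted internally; note that
m/s and mm/ms coincide, so 1540 m/s is 1.54 mm/µs.

The default geometry mirrors a 128-element, 0.22 mm pitch, 3 MHz phased
array (total aperture footprint D = n * pitch = 28.16 mm) driven with a
single-cycle excitation, the configuration all bundled experiments use.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TransducerArray",
    "Medium",
    "Pulse",
    "make_array",
    "single_cycle_pulse",
    "tone_burst",
    "gaussian_pulse",
    "emitted_pulse",
]


@dataclass(frozen=True)
class TransducerArray:
    """Uniform 1-D phased array centered on x = 0 in the z = 0 plane."""

    n_elements: int
    pitch: float              # mm, element-to-element spacing
    element_width: float      # mm, active width of one element (<= pitch)
    center_frequency: float   # MHz

    def __post_init__(self) -> None:
        if self.n_elements < 2:
            raise ValueError("n_elements must be >= 2")
        if self.pitch <= 0:
            raise ValueError("pitch must be positive")
        if not (0 < self.element_width <= self.pitch):
            raise ValueError("element_width must lie in (0, pitch]")
        if self.center_frequency <= 0:
            raise ValueError("center_frequency must be positive")

    @property
    def element_x(self) -> np.ndarray:
        """Element-center lateral positions (mm), symmetric about 0."""
        n = self.n_elements
        return (np.arange(n) - (n - 1) / 2.0) * self.pitch

    @property
    def aperture(self) -> float:
        """Total aperture footprint D = n * pitch (mm)."""
        return self.n_elements * self.pitch


@dataclass(frozen=True)
class Medium:
    """Homogeneous propagation medium.

    Parameters
    ----------
    sound_speed
        Speed of sound in m/s (default 1540, the soft-tissue convention).
    attenuation
        Amplitude attenuation coefficient in dB/cm/MHz, applied at the
        carrier frequency along each propagation path; default 0 (water).
    """

    sound_speed: float = 1540.0
    attenuation: float = 0.0

    def __post_init__(self) -> None:
        if self.sound_speed <= 0:
            raise ValueError("sound_speed must be positive")
        if self.attenuation < 0:
            raise ValueError("attenuation must be >= 0")

    @property
    def c(self) -> float:
        """Sound speed in mm/µs."""
        return self.sound_speed * 1e-3

    def wavelength(self, frequency: float) -> float:
        """Wavelength (mm) at `frequency` (MHz)."""
        return self.c / frequency


@dataclass(frozen=True, eq=False)
class Pulse:
    """Sampled excitation waveform, unit peak amplitude.

    The waveform is defined on [0, duration) and evaluates to zero outside;
    `__call__` interpolates linearly at arbitrary times.
    """

    center_frequency: float   # MHz
    n_cycles: float           # carrier cycles contained in the waveform
    sampling_rate: float      # MHz
    samples: np.ndarray = field(repr=False)

    @property
    def duration(self) -> float:
        """Pulse duration n_cycles / f0 (µs)."""
        return self.n_cycles / self.center_frequency

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sampling_rate

    def __call__(self, times: np.ndarray) -> np.ndarray:
        times = np.asarray(times, dtype=float)
        out = np.interp(times.ravel(), self.t, self.samples, left=0.0, right=0.0)
        return out.reshape(times.shape)


def make_array(
    n_elements: int = 128,
    pitch: float = 0.22,
    f0: float = 3.0,
    element_width: float | None = None,
) -> TransducerArray:
    """Build a uniform phased array; `element_width` defaults to 0.9 * pitch."""
    if element_width is None:
        element_width = 0.9 * pitch
    return TransducerArray(
        n_elements=int(n_elements),
        pitch=float(pitch),
        element_width=float(element_width),
        center_frequency=float(f0),
    )


def _sampled_burst(f0: float, fs: float, n_cycles: float) -> np.ndarray:
    if fs < 10 * f0:
        raise ValueError(
            f"sampling_rate {fs} MHz too low for f0 = {f0} MHz (need >= 10 f0)"
        )
    duration = n_cycles / f0
    n = int(round(duration * fs))
    t = np.arange(n + 1) / fs
    s = np.sin(2 * np.pi * f0 * t)
    s[t >= duration] = 0.0
    return s


def tone_burst(f0: float, fs: float = 100.0, n_cycles: float = 1.0) -> Pulse:
    """Sine burst of `n_cycles` full carrier cycles, peak amplitude 1."""
    s = _sampled_burst(f0, fs, n_cycles)
    s = s / np.max(np.abs(s))
    return Pulse(center_frequency=float(f0), n_cycles=float(n_cycles),
                 sampling_rate=float(fs), samples=s)


def single_cycle_pulse(f0: float, fs: float = 100.0) -> Pulse:
    """One full sine cycle at `f0` — the standard imaging excitation here."""
    return tone_burst(f0, fs, n_cycles=1.0)


def emitted_pulse(
    f0: float,
    fs: float = 400.0,
    excitation_cycles: float = 1.0,
    impulse_response_cycles: float = 4.0,
) -> Pulse:
    """Effective acoustic pulse: excitation convolved with the transducer.

    The electrical excitation is a hard-gated sine burst
    (`excitation_cycles`, default a single cycle) and the transducer's
    electro-mechanical impulse response is modeled as a Hann-windowed sine
    burst of `impulse_response_cycles`.  Their convolution is the pressure
    waveform each element actually radiates.  The default impulse-response
    length reproduces the resolved first-order side-lobe structure of a
    focused unapodized aperture (distinct lobes a little below the
    continuous-wave -13.3 dB level); a fully broadband point excitation
    would fill the diffraction nulls completely and leave no measurable
    side lobes.
    """
    exc = _sampled_burst(f0, fs, excitation_cycles)
    imp = _sampled_burst(f0, fs, impulse_response_cycles)
    imp = imp * np.hanning(imp.size)
    s = np.convolve(exc, imp)
    s = s / np.max(np.abs(s))
    n_cycles = excitation_cycles + impulse_response_cycles
    return Pulse(center_frequency=float(f0), n_cycles=float(n_cycles),
                 sampling_rate=float(fs), samples=s)


def gaussian_pulse(f0: float, fs: float = 100.0, n_cycles: float = 2.5) -> Pulse:
    """Gaussian-windowed sine burst (optional smoother excitation).

    The envelope is a Gaussian truncated at +/- 3 sigma across the burst,
    which approximates a band-limited transducer response better than the
    hard-gated single cycle; zero mean is enforced exactly.
    """
    s = _sampled_burst(f0, fs, n_cycles)
    t = np.arange(s.size) / fs
    duration = n_cycles / f0
    sigma = duration / 6.0
    env = np.exp(-0.5 * ((t - duration / 2) / sigma) ** 2)
    s = s * env
    s -= s.mean()
    s = s / np.max(np.abs(s))
    return Pulse(center_frequency=float(f0), n_cycles=float(n_cycles),
                 sampling_rate=float(fs), samples=s)
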