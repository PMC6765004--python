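# Methods

## Physical model

The simulator is a linear, 2-D (lateral × axial) time-domain model of a
1-D phased array radiating into a homogeneous medium.

**Aperture.** Each element of width `w` is subdivided into point
sub-sources no wider than λ/8 (four per element at the defaults), so
element directivity emerges from the sub-source sum rather than from an
explicit obliquity factor. Spreading is spherical (1/R) with no baffle
term. The pressure at a field point is

    p(t) = Σ_s a_s / R_s · u(t − τ_s − R_s/c),

with `a_s` the element apodization split over its sub-sources, `τ_s` the
element delay and `u` the emitted pulse. Optional frequency-independent
attenuation multiplies each path by `10^(−α f₀ R / 20)` (α in dB/cm/MHz,
default 0, i.e. water).

**Field value.** Maps and profiles store the temporal peak of the envelope
(magnitude of the analytic signal along time), the convention of
peak-pressure hydrophone scans. Profiles are normalized to their own
maximum and expressed in dB.

**Emitted pulse.** The electrical drive is a single-cycle sine, but the
radiated waveform is band-limited by the transducer. `emitted_pulse`
models this as the drive convolved with a Hann-windowed sine burst
(the electro-mechanical impulse response), default length 4 carrier
cycles. This default is deliberate: a raw one-cycle pulse (~100 %
fractional bandwidth) fills the diffraction nulls completely, leaving a
profile that decays monotonically away from the main lobe with *no*
measurable first-order side lobes — at which point side-lobe positions,
levels and their optimization are undefined. With the 4-cycle response the
unapodized 60 mm profile shows the canonical structure of a focused
rectangular aperture: resolved side lobes at ±1.63 mm at −15.9 dB (the
band average dips below the continuous-wave −13.3 dB), a 0.99 mm −3 dB
main lobe, and a Hamming width of 1.46 mm. `single_cycle_pulse`,
`tone_burst` and `gaussian_pulse` are available for experiments with other
bandwidths.

**Units.** Lengths in mm, times in µs, frequencies in MHz; sound speed is
entered in m/s (default 1540, the soft-tissue convention — the value is
not critical and is configurable). Element width defaults to 0.9 × pitch
(kerf unspecified by typical data sheets; it only mildly shapes element
directivity at the angles involved). The simulation time axis is sampled
at 100 MHz (pulse lookup tables at 400 MHz, making interpolation error of
the table lookup ≈ −70 dB); the wide-span grating-lobe analysis uses
40 MHz, ample for envelope peaks.

## Two-foci design and the interlaced transmission

The two-foci waveform is designed with the pseudo-inverse method at the
carrier frequency: build the propagation row matrix
`H[k,i] = exp(−j 2π f₀ R_ki / c) / R_ki` from every element `i` to each
focus `k` and solve `w = pinv(H) · 1` for the minimum-norm element weights
producing equal unit pressure at both foci. Delay/apodization hardware
cannot apply complex weights directly, so they are re-encoded as
`apod = |w| / max|w|` and a delay carrying `arg(w)`.

Two conventions here are load-bearing:

1. **Common focal clock.** The phase-to-delay conversion is referenced to
   `t_ref = max_i R_i(foci centroid)/c` — the same instant at which the
   single-focus law (min delay 0 at the edge elements) delivers its focal
   peak. Both interlaced waveforms therefore arrive carrier-phase-coherent
   at the focal plane, which is what makes a purely *real* amplitude
   coefficient `c` sufficient for destructive interference. Re-normalizing
   the two-foci delay map (e.g. min-shifting it to 0) would rotate that
   phase arbitrarily and break the cancellation.
2. **Period unwrapping toward the geometric law.** `arg(w)` is only
   defined modulo one carrier period T. The ambiguity is resolved by
   choosing, per element, the delay closest to the smooth single-focus
   law at the foci centroid; the π sign flips of the two-foci fringe
   pattern then appear as ±T/2 offsets while the broadband pulses stay
   time-aligned across the aperture. (A raw wrap into [0, T) scrambles
   the pulse-time alignment for short pulses and moves the field maxima
   off the foci entirely.) A consequence is that the minimum delay of a
   phase-encoded scheme is near, but not exactly, zero.

Interlacing takes delays and apodization verbatim from the single-focus
scheme on the odd elements (1-based ordinal position; element 1 at the
most negative lateral coordinate — for symmetric designs the choice of
end is immaterial) and from the two-foci scheme, apodization scaled by
`c`, on the even elements. The two-foci design is computed on the full
aperture and then restricted by the interlace; for steered transmissions
the foci are offset perpendicular to the beam axis at the same range.

## The (c, Δx) optimization

The objective for a candidate `(c, Δx)` is the level of the interference
minimum that the interlaced profile develops at the first-order side-lobe
positions of the unmodified single-focus profile: the candidate profile is
evaluated within ±0.1 mm (≈ λ/5) of each fixed baseline side-lobe
position, the minimum of each window is taken, and the larger (worse) of
the two sides — in dB relative to the candidate's own main-lobe peak over
|x| ≤ 0.45 mm — is returned. The narrow window matters physically: the
focal plane carries a quadratic carrier phase (≈ −π x²/(λz), about −16°
at 1.6 mm/60 mm), so the true null sits a fraction of a wavelength off
the geometric side-lobe peak; reading only the fixed point caps the
apparent cancellation several dB short of the null. `window=0` recovers
the strict fixed-position reading (and makes the `c = 0` objective equal
the baseline side-lobe level exactly).

The search is a plain Cartesian grid — the surface contains narrow
interference nulls that defeat gradient methods — over `c ∈ [0, 0.6]`
step 0.01 and `Δx ∈ [2, 4]` mm step 0.05 at the 60 mm design depth. It
exploits linearity: the time-domain pressure of the interlaced scheme is
exactly `p_odd + c · p_even(Δx)`, so the odd-element traces are simulated
once, the even-element traces once per Δx, and the entire `c` axis costs
only complex arithmetic on cached analytic signals (the full 61 × 41 grid
runs in a few seconds). At 60 mm the argmin is (c = 0.37, Δx = 3.0 mm) at
−24.5 dB, stable under halving both grid steps.

`optimize_for_depth` scales the default Δx grid with depth:
`[2(x_sl − 0.5), 2(x_sl + 0.5)]` mm around twice the measured baseline
side-lobe offset `x_sl`, reflecting the design intent that the canceling
foci overlap the side lobes they cancel (at 60 mm this coincides with the
fixed [2, 4] mm grid). Without this restriction a deeper-lying spurious
solution exists at large `c` and small Δx whose foci are nowhere near the
side lobes — a qualitatively different (and main-lobe-degrading) regime.

## Imaging chain

Channel data use a first-order Born (single-scattering) model with point
elements: the transmit field is evaluated at each scatterer and
re-radiated spherically to every receive element; receive-element
directivity and a receive bandpass are deliberately omitted (side-lobe
structure is delay-driven). Beamforming is conventional delay-and-sum
with dynamic receive focusing along each steered scanline: the transmit
wavefront is assumed to pass range r on the beam axis at
`t_focal + (r − r_focal)/c` (virtual-clock model), range sampling is
`c/(2·4f₀)`, receive apodization is rectangular over the full aperture,
and the emitted pulse's envelope-peak lag is compensated so echoes map to
the scatterer range. Scanlines are envelope-detected (analytic signal
along range), scan-converted to a 0.05 mm Cartesian grid by bilinear
interpolation, and log-compressed to a 0 dB peak with a 50 dB default
display range. Images keep the linear envelope alongside the display
pixels; contrast and CNR are computed on the linear envelope, as their
amplitude-ratio definitions require.

Default sector: 18° field of view; 128 angles for wire targets (0.14°
step samples the PSF finely), 64 for the speckle cyst.

## Synthetic phantoms — what they emulate and what they do not

- `single_wire`: one unit point target (a 50 µm nylon wire is far below
  the 0.51 mm wavelength, hence a point).
- `resolution_phantom`: eleven wires in an L — an axial and a lateral
  chain sharing the corner wire at the focal depth, successive gaps 4, 3,
  2, 1, 0.5 mm.
- `cyst_phantom`: uniform random scatterer positions with zero-mean
  Gaussian reflectivities and an excised anechoic disc (default radius
  4 mm at 70 mm depth). Default density 15 /mm² ≥ 5 scatterers per
  resolution cell (≈ 1.2 mm lateral × 0.26 mm axial at 70 mm), the
  accepted threshold for fully developed speckle; the beamformed
  background indeed shows envelope SNR ≈ 1.9 (Rayleigh). Deterministic
  given a seed.

The phantoms emulate idealized experiments: no elevation dimension, no
attenuation or aberration by default, no electronic noise, no transducer
receive response, and scatterers are static points. Passing tests
therefore demonstrate the *beam physics* of the method — side-lobe
cancellation, resolution preservation, grating-lobe behavior, contrast
mechanics — not its performance under tissue inhomogeneity or noise.
Contrast/CNR follow the circular-ROI convention: lesion ROI radius 0.7 ×
cyst radius centered on the cyst, equal-area background ROI at the same
depth offset laterally (−6.5 mm default).

## Numerical choices

- Envelope via `scipy.signal.hilbert`; field amplitude = temporal peak.
- Main-lobe widths from linearly interpolated level crossings nearest the
  peak; side-lobe peaks refined with a 3-point parabola.
- The main lobe is bounded by the first local minima flanking the global
  peak; first-order side lobes are the nearest outside maxima
  (prominence ≥ 0.5 dB to skip numerical ripple); a monotone profile
  yields an empty side-lobe list rather than an error.
- Degenerate inputs raise `ValueError` early: non-positive geometry,
  field points at z ≤ 0 or coincident with a source, empty/unsorted
  grids, ROIs outside the image, zero-variance CNR.
- Auto-sized time windows per depth row keep traces short; all stages are
  deterministic, and the only randomness (speckle) is seeded.

## Known limitations

- **Cancellation depth saturates near −25 dB.** With the 4-cycle emitted
  pulse the best achievable null at the side-lobe positions is ≈ −24.5 dB
  (from −15.9 dB, an ≈ 8.6 dB reduction; measured hardware reductions
  reported for this class of method are of the same order). The limit is
  structural for this model: the single-focus side-lobe waveform is
  temporally stretched by aperture edge waves while the two-foci focal
  waveform is compact, so even an optimal *complex* coefficient leaves a
  ≈ −25 dB envelope residual. Narrower-band (8–10 cycle) pulses cancel
  past −32 dB but then the baseline side-lobe level itself rises toward
  the CW value, trading away the baseline agreement. Richer simulators
  (3-D apertures with an elevation lens and a measured impulse response)
  can report deeper one-way nulls than this 2-D line-source model.
- **The Δx valley is shallow.** Around the optimum the objective varies
  by < 0.1 dB over several tenths of a millimetre of Δx, so the argmin's
  Δx is weakly identified — at 70 mm the depth-scaled search settles at
  Δx ≈ 3.9 mm (c ≈ 0.35) on an essentially flat valley floor. The
  coefficient `c` is much better determined, and the depth ordering
  (optimal Δx grows with focal depth) is robust.
- Single-scattering receive model; no tissue attenuation/aberration in
  the bundled experiments; 2-D geometry throughout; the interlace parity
  is fixed to element index, so steered interlaced fields are mirror
  symmetric only to within a few percent (even element counts swap
  parity under reflection).
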