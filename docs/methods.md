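# Methods

This note documents the models behind each module, the defaults and why
they were chosen, the numerical conventions, and what the synthetic data
does and does not establish about real recordings.

## Synthetic myoelectric signals

Volitional surface EMG is synthesized as Gaussian white noise band-passed
with a 4th-order Butterworth filter over 20–450 Hz, normalised per channel
to unit whole-trace RMS, and amplitude-modulated by
`activation(t) × emg_rms_at_full_activation`. This is the standard
phenomenological surrogate for interference-pattern surface EMG: it
reproduces the band-limited, zero-mean, amplitude-modulated statistics the
envelope estimator assumes, and nothing more. It deliberately omits
motor-unit structure, volume conduction, electrode geometry and
non-stationarity of the spectrum — so tests passing on it show that the
*processing chain* behaves as specified, not that envelope estimates on a
particular patient will be equally clean.

Defaults (all configurable): sampling rate 1 kHz (the band's upper corner
at 450 Hz leaves Nyquist margin); full-activation RMS 0.5 mV (the scale of
healthy-subject surface EMG at strong contraction; paretic muscle will sit
far lower, which only rescales offsets and gains); mains 50 Hz at 0.1 mV;
movement artifacts as a Poisson process (0.1 events/s) of ±2 mV baseline
steps recovering with τ = 0.5 s — the simplest model of a disturbed
electrode half-cell potential. The M-wave is a damped sinusoid (latency
8 ms, τ = 10 ms, 80 Hz carrier) with a clipped-logistic amplitude in
current; with these constants it decays below 1% of its peak well inside
one 60 ms stimulation period, which the blanking/filtering design assumes.
All randomness descends from one seed through per-component
`SeedSequence` spawns, so traces are bit-reproducible and the four
components superpose linearly.

## Stimulation engine

The doublet waveform is built on a sample grid: each biphasic pulse is two
phases of equal integer sample count and opposite sign, so the per-period
integral is exactly zero — charge balance holds to time-quantisation
precision by construction rather than by numerical cancellation. Waveform
polarity is cathodic-first (configurable; a convention, not a measured
property). The intra-doublet gap (5 ms) and the channel stagger (T/2 =
30 ms) are design choices: the stagger is symmetric to maximise the
artifact-free sampling window on each channel, and both are configuration,
not constants. DAC quantisation is round-to-nearest onto multiples of
`full_scale / 2^bits`; a value that would exceed the safety limit is
replaced by the largest step multiple not exceeding it, so the limit is
never crossed (quantisation is therefore idempotent and limit-respecting).
A resistive load exposes the compliance bound `min(limit, V_compliance/R)`.

## Firmware chain

The firmware stages are pinned in the order **blank → comb → windowed RMS →
smooth → control law**. The ordering rationale: blanking first makes the
comb's input periodic wherever the artifact is period-synchronous
(including the blanking windows themselves), so the lag-T comb cancels it
exactly; RMS then sees only aperiodic content. The comb is the feed-forward
first difference at lag N = T·fs (zero-padded head), chosen for its exact
nulls at DC and k/T — with T = 60 ms and 50 Hz mains, three full mains
cycles fit one lag, so mains rejection is exact, not approximate. The
envelope is one RMS value per stimulation period over the non-blanked
samples (blanked samples excluded from both sum and count), matching the
frame rate at which commands can take effect. "Smoothing" is first-order
exponential with `a = exp(−T/τ)`, τ = 0.2 s by default — a choice; the
smoother's DC gain is one, so it shapes transients without affecting
steady-state scaling. In the control law the offset subtraction is
rectified (`max(V−Off, 0)`) *before* the signed gain matrix: offsets
represent involuntary background to be denoised away, and stimulation
current cannot be negative, while negative cross-gains must still be able
to subtract genuine supra-offset antagonist activity.

Blanking is tied to each pulse onset; with the 20 ms default it covers both
pulses of a doublet (gap 5 ms + pulse span 0.6 ms < 20 ms).

## Closed loop, watchdog and stability

The feedback path is modelled at the envelope level: the measured envelope
of period k is the volitional envelope plus `c · I(k−1)` with `c` the
residual artifact coupling (mV/mA) surviving blanking and comb filtering,
plus optional Gaussian measurement noise. One period of transport delay
makes the noiseless, unclamped, offset-linearised loop an exact geometric
recursion `I(k) = G_eff · I(k−1)` with `G_eff = G·c`, so the stability
dichotomy (decay below 1, clamp above 1) is closed-form checkable and the
bisection search must land at 1 within its resolution. The magnitude of `c`
in real recordings is not characterised here; it is a swept parameter, and
a sample-level mode (generator + firmware pipeline inside the loop) is
provided for integration checks — with zero coupling it reproduces the
open-loop chain exactly.

`find_critical_gain` classifies a run as unstable only when the impulse
response reaches and holds ≥95% of the current limit; a marginal run
(product exactly 1) neither grows nor decays and is classified stable, so
the bisection converges to the boundary from above. The analysis runs with
offsets zeroed (linearisation above the operating point), smoothing off
(unity DC gain, irrelevant to the boundary) and quantisation off (the DAC
deadband would artificially stabilise small signals).

The watchdog accumulates time while the command is at ≥95% of the limit
(default) and trips after 5 s, forcing the channel to zero. These two
thresholds are engineering defaults, not measured device values. The trip
latches: it releases only when the measured envelope falls below the re-arm
threshold, and tripping clears the channel's smoother state so a re-armed
channel restarts from zero instead of re-entering latch-up from the
remembered envelope — without this reset an unstable configuration would
re-trip periodically instead of staying safely off.

## Applicator kinematics

The forearm's pronation/supination is reduced to a single-axis
approximation: for rotation angle θ the proximal ring's anchors rotate by θ
about the central axis while the distal ring's anchors rotate by θ about an
axis offset one-quarter of the wrist width externally and one-quarter of
the wrist height posteriorly from the section centre ("one quarter" is
interpreted against each respective wrist dimension; both the fraction and
the reference are configurable). The relative bar motion therefore comes
entirely from the eccentricity between the two axes. The composite motion
of the radius within the sigmoid cavity is not modelled; results should be
read as bounds produced by this approximation, and the geometry assumptions
are embedded in the exported summary metadata.

The PP section is a circle at the measured circumference; the DP section is
an ellipse with the wrist width and height as its axes. Four bars anchor at
parametric angles ±45°/±135° on both rings — a symmetric choice that keeps
the dorsal and volar midlines free for straps and finger access. Bars are
rigid with ball-socket ends; axial translation between the parts is
permitted by the sliding mechanism, so the computed anchor-distance
variation is the slack that mechanism must absorb, and the socket travel is
the angle between a bar's direction at θ and its reference direction. That
deflection measure is taken in the laboratory frame, so in the degenerate
coaxial case it reduces to the pure twist of the tilted bar
(`cos α = (|d₀|²cos θ + L²)/(|d₀|² + L²)`), not to zero. Sweeps run at 1°
resolution by default; the distance-variation and travel quantities are
maxima over bars.

With the defaults (separation 180 mm, wrist 40 × 60 mm, PP circumference
250 mm) the full 0–110° sweep gives 3.56 mm of distance variation and
16.7° of worst-bar socket travel — inside the 15–20° socket range the
two-part design is dimensioned for.

## Numerical conventions and degenerate inputs

Units are fixed package-wide: seconds, mV, mA, mm, degrees. Envelope
values are non-negative by definition; a fully blanked window yields 0 with
a warning rather than NaN. The comb's first N outputs are zero by
convention. Event times are snapped to the nearest sample. CSV is the
canonical interchange (floats at %.17g, bit-exact round trip); EDF export
uses plain 16-bit EDF with a symmetric physical range just above the
per-file maximum, so round trips are exact to `range/2¹⁶` — the writer and
reader are implemented here and cross-validated against MNE's independent
EDF reader in the tests.

## Problem sizes

Default test and analysis runs use seconds-to-minutes of simulated signal
at 1 kHz and per-period loop simulations of a few thousand steps; the
bisection stability search uses 120 s horizons per probe. These sizes make
every statistical check (RMS tracking at 5%, Poisson event counts,
envelope-recovery tolerances) comfortably converged while keeping the full
suite in a few seconds.

## Known limitations

- The EMG surrogate has no motor-unit or volume-conduction structure, and
  the impedance dependence of artifact amplitude is a free parameter, not a
  mechanistic model.
- The residual envelope coupling `c` is not identified from data; latch-up
  results are parametric in it.
- Watchdog thresholds, intra-doublet gap, channel multiplexing order and
  the smoother form are documented engineering choices where the device
  firmware's exact values are not public.
- The kinematic model collapses the radius-around-ulna composite motion to
  one offset axis per ring; its 5 mm / 15–20° figures are bounds under that
  approximation, not anatomical measurements.
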