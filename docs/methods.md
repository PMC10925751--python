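# Methods

## Wavelet packet engine

The core transform is a full (both-branch) wavelet packet decomposition
implemented as a recursive two-channel filter bank. One analysis step is a
periodized convolve-and-downsample,

    a[j] = Σ_k f[k] · x[(2j + L/2 − k) mod n],

applied with the low-pass taps `h` and the high-pass taps `g` to every node
at every level. Periodization (circular boundary handling) is the only
boundary mode under which the finite transform is exactly orthogonal, which
gives machine-precision Parseval energy conservation; symmetric or
zero-padded extensions would leak energy at the boundaries. The index
convention above was chosen to coincide with PyWavelets'
`mode="periodization"`, so the terminal coefficient arrays can be compared
against that library to 1e-10 in the tests without any realignment.

The shipped basis is Symlet-2: four taps, orthogonal, minimal support. Its
taps are frozen as decimal literals and re-checked against the orthonormal
QMF identities (Σh = √2, Σh² = 1, shift-orthogonality, alternating-flip
high-pass) every time a `QMFPair` is constructed. The high-pass follows the
filter-bank convention `g_k = (−1)^(k+1) h_{L−1−k}`, which is the two-scale
relation `g_k = (−1)^k h_{1−k}` up to an even circular shift and a global
sign; the tests check membership in that family. Any other orthogonal pair
can be supplied through `QMFPair`.

Signals are zero-padded at the tail to a multiple of `2^levels` samples
(impact windows at 5000 Hz are often shorter than 512 samples). Zero padding
adds no energy, so band energies are unaffected in aggregate; it does change
the periodization circle, which is why tone-localization tests use signal
lengths that are already block-multiples.

Terminal nodes emerge in natural (filter-path) order; every high-pass branch
folds the spectrum, so children of high-pass nodes are frequency-reversed.
The natural-to-frequency permutation is the Gray-code-to-binary map
(cumulative XOR over path bits), verified in the tests both against a
four-tone oracle at depth 2 and against PyWavelets' `order="freq"` listing.
Band indexing is 0-based with half-open intervals `[j·Δf, (j+1)·Δf)`,
`Δf = fs/2^(level+1)`, so index times band width is the band's lower edge.

**Known limitation — dyadic-edge leakage.** A 4-tap filter has wide
transition bands. After nine iterations, the effective band-pass responses
overlap strongly near the coarse-level band crossovers (multiples of
fs/16 = 312.5 Hz at the default rate): a pure tone within ~30 Hz of such a
crossover can peak several bands away from the ideal-band-pass prediction.
This is a property of the sym2 basis, not of the implementation — the
reference library places those tones in the identical band (a dense
400-tone sweep shows 8/400 misses, all inside those crossovers). The
tone-localization tests therefore exclude a 32 Hz guard band around the
crossovers and separately assert implementation–reference agreement inside
them. Away from crossovers, localization is within ±1 band.

## Indicators and HIC

The three frequency-domain indicators are direct functionals of the energy
vector: peak band energy, its (frequency-ordered, 0-based) index with both
Hz edges, and its share of total energy. Exact ties break toward the lowest
band index; an all-zero spectrum raises an explicit degenerate-signal error
rather than returning 0/0.

HIC is computed by exhaustive search over sample-aligned windows using a
cumulative trapezoidal integral, so a window average costs O(1) and the
whole search O(n·w) for w samples per maximal window. This is verified
against an independent O(n²) all-pairs search to 1e-9 relative. The window
cap defaults to 15 ms (HIC15) and is configurable (e.g. 36 ms). Acceleration
is always converted to g internally (9.80665 m/s² per g); signed samples are
integrated by default, and a maximizing window with negative mean
contributes |mean|^2.5 with a warning. Sub-sample window optimization is
not attempted; at 5000 Hz the alignment error is negligible.

## Synthetic impact generator

The generator emulates a factorial campaign of cylinder-to-head blunt
impacts with a three-degree-of-freedom surrogate:

* **Block**: rigid mass `m_b = π (d/2)² t ρ` from the factor levels
  (diameters 12.5/25/37.5 mm, thickness 12 mm; rubber/glass/steel densities
  1.829e-6 / 2.5e-6 / 7.8e-6 kg/mm³). "d×t" is read as diameter ×
  thickness; a 12.5 mm *radius* reading would change areas fourfold.
* **Contact**: the block's axial stiffness `E·A/t` (E = 4 / 70 000 /
  210 000 MPa) in series with an area-scaled scalp stiffness
  (`E_scalp·A/t_scalp`, 20 MPa / 6 mm), active only in compression, plus a
  viscous scalp term `η·A/t_scalp` (η = 2000 Pa·s) during contact, with the
  total contact force clamped non-negative (contact cannot pull). Two
  consequences drive the study's contrast: soft impactors are
  contact-*over*damped (a long, gentle, low-frequency push) while stiff
  ones stay underdamped (a short, sharp pulse), and the series scalp term
  caps every contact resonance below the 2500 Hz Nyquist frequency so the
  sampled surrogate is alias-free.
* **Head**: a 1.2 kg directly-impacted shell coupled to a 3.3 kg interior
  mass (4.5 kg total) by a spring-damper with the coupled mode at 25 Hz —
  inside the 14–35 Hz head fundamental range — and 4 % damping; the shell
  is weakly grounded (3 Hz mode) to represent the occipital fixation.
  Impact position multiplies the contact stiffness by 0.9/1.0/1.1
  (right/front/top), a deliberately weak effect so that position behaves as
  the null factor it is in head-impact sensitivity studies.

The equations of motion are integrated with fixed-step classical RK4 at a
step of at most `1/(50·f_max)` (f_max = fastest linearized mode), aligned so
that output samples at 5000 Hz fall on integration steps. A
total-mechanical-energy gain above 1 % aborts the run as unstable; with all
damping removed the integrator conserves energy to better than 0.1 % over a
run (tested). Optional additive white Gaussian noise at a configured SNR is
drawn from the per-scenario seed; the default is noise-free, matching
deterministic solver output. Because every force law is homogeneous of
degree one in the state and the contact switching conditions are
sign-based, the response scales exactly linearly with impact velocity —
peak sub-band energy as v² and HIC as v^2.5 — which makes the velocity
trends in the factorial study exact rather than statistical.

All head-side constants are calibration choices of this package (no
redistributable head-impact dataset fixes them). They were chosen once so
that the default factorial reproduces the qualitative pattern expected of
such campaigns: low-speed rubber impacts concentrate energy below 100 Hz
while high-speed steel impacts do not; peak sub-band energy and HIC rise
strictly with velocity and with impactor stiffness; position is
non-significant. What passing tests show is that the *analysis pipeline*
recovers these built-in contrasts, not that the surrogate reproduces any
particular finite-element head model; tissue-level quantities (e.g. maximum
principal strain) are outside the surrogate entirely and enter only as an
externally supplied column.

## Statistics

Factor effects are tested marginally: for one factor, the 81 rows are pooled
into its three level groups (27 each) and compared with the Kruskal–Wallis
rank test (mid-ranks with tie correction, chi-square approximation). The
rank test was chosen because responses span orders of magnitude across the
design and no distributional form is defensible; its type-I error at the
3×30 design is verified by simulation (≈0.048 at α = 0.05). p-values are
reported raw, one per factor-response cell, without multiple-testing
correction. Responses with a single distinct value are excluded from
testing (the rank statistic is undefined under total ties).

Responses are min-max normalized to [0, 1] for joint display (z-scoring is
available behind a flag); constant columns are rejected. Indicator–HIC
relations use ordinary least squares with `R² = 1 − SS_res/SS_tot`; a
constant x is an error (undefined slope) and a constant y returns R² = 0
with a degenerate-fit warning.

## Problem sizes and defaults

| Parameter | Default | Why |
|---|---|---|
| Sampling rate `fs` | 5000 Hz | resolves impact peaks; Nyquist 2500 Hz |
| Decomposition depth | 9 | 512 bands of 4.88 Hz over [0, 2500 Hz) |
| Signal duration | 0.2 s | captures the contact pulse plus several ring-down cycles at 25 Hz |
| HIC window cap | 15 ms | HIC15; 36 ms variant configurable |
| Factorial design | 3⁴ = 81 | full crossing of position, material, velocity, size |
| dt jitter tolerance | 0.1 % | accepts solver-jittered output times, rejects resampled files |
| Energy-conservation tolerance | 1e-8 relative | machine-precision transform plus accumulation slack |

The acceptance script re-runs the transform checks on 100 random signals,
the coefficient oracle on 12 length/depth combinations, 20 tones, 50 HIC
pulses, the full 81-run factorial, and 200 null replicates of the rank
test; the whole script completes in well under a minute on one core.
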