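# Methods

This note records the models, numerical choices and their rationale, what
the synthetic instrument does and does not emulate, and the known limits
of the package.

## Decay model and incomplete-decay wrap

Fluorescence decays are multi-exponential,
`I(t) = I0 Σ αᵢ e^(−t/τᵢ) + C`, with amplitude (pre-exponential)
fractions `αᵢ` summing to one, lifetimes in ps, and a constant per-bin
background `C`. With pulsed excitation at repetition period `T` (default
25 ns, i.e. 40 MHz), emission from previous pulses overlaps the current
period; because the sum over pulses is geometric, each component's
per-period profile is exactly `e^(−t/τ)/(1 − e^(−T/τ))`. This closed form
is used everywhere (no truncated sums, no extra fitted "offset from
previous pulses" parameter). Because excitation is periodic, model ⊗ IRF
is computed as a *circular* convolution over the period via FFT, which is
exact rather than an approximation, and conserves counts because IRF
kernels are unit-sum.

Amplitude convention: `αᵢ` are amplitude fractions; for simulation, `I0`
is chosen so the noise-free curve minus background sums to the photon
budget, so "10⁶ photons" means an expected 10⁶ detected photons per
histogram.

## Acquisition defaults

| parameter | default | why |
|---|---|---|
| `n_bins` × `bin_width` | 4096 × 6.1035 ps ≈ 25 ns | spans exactly one 40 MHz period |
| `rep_period` | 25 000 ps | 40 MHz excitation |
| IRF shape | Gaussian, unit-sum, centred 1000 ps into the window | only FWHM is known for real detectors; 1 µs-scale placement irrelevant, 1000 ps leaves the rising edge fully sampled |
| IRF FWHM | 200 ps or 35 ps | the two detector classes emulated (cooled PMT vs hybrid PMT) |
| photon budget | 10⁶ | typical cuvette TCSPC acquisition |
| analysis window | from 10 bins before the histogram peak, 12.5 ns long | window lengths of 11–15 ns are standard for these decays; the exact anchor is a free choice, so it is pinned to the peak deterministically |

Reference decay parameter sets used as simulation ground truth:
free NADH 25 °C (266, 781 ps; α₁ = 0.793), free NADH 37 °C (252, 683 ps;
α₁ = 0.81), fully LDH-bound NADH (804, 2503 ps; α₁ = 0.851).

## Fitting

Weighted nonlinear least squares. Weights start as Neyman weights
`1/max(counts, 1)` — the standard TCSPC χ² weighting — but pure Neyman
weighting is biased when the window contains low-count tail bins (a bin
that fluctuates low is over-weighted): at 10⁶ photons this biased τ₂ by
≈ −22 ps and τ₁ by ≈ −7 ps in our simulations. `fit_decay` therefore
performs two iteratively-reweighted passes with model-based Poisson
weights `1/max(model, 1)` after the Neyman-weighted solution; residual
bias is ≈ 1 ps. A consequence of clamping the variance at 1 in near-empty
bins is that the reported reduced χ² of a correct model sits below 1
(≈ 0.6 at these budgets); it is a relative fit-quality index here, not an
absolute probability statement.

Parametrization: lifetimes are optimized on a log scale; fractions through
bounded stick-breaking variables in [0, 1]; the overall amplitude and the
background are profiled out at every step by a weighted linear solve
(variable projection, with non-negativity enforced), leaving ≤ 5 nonlinear
parameters for the trust-region-reflective optimizer. The IRF shift `t0`
is applied as a Fourier-domain phase ramp, so it is continuous and exact
for the circular model; `t0` is either co-fitted (reference decays) or
fixed (all other decays of a batch), mirroring daily-IRF practice.

Five dispersed initial lifetime guesses (multiples of a center-of-mass
lifetime estimate) guard against local minima; the loop stops early when
reduced χ² < 1.05, so clean fits cost one start. Everything is
deterministic. Lifetimes are sorted after fitting (label-switching
tie-break); exactly coincident lifetimes from degenerate fits are nudged
apart by 1e−9 relative to keep the strict ordering convention. Standard
errors come from a finite-difference Jacobian in natural parameters
(τᵢ, αᵢ, I0, C, t0) via (JᵀJ)⁻¹ with the final weights.

The free/bound decomposition fixes both two-component shapes entirely
(unit-area normalised over the period, so the mixing weight *is* the
detected-intensity bound fraction) and solves the remaining problem —
linear in (I0(1−f), I0·f, C) — by weighted non-negative least squares.
This is exact, has no starting-value sensitivity, and enforces
0 ≤ f ≤ 1 by construction.

## Anisotropy

Channels follow photoselection: `Ipar = ⅓ I(t)(1 + 2r(t))`,
`Iperp = ⅓ I(t)(1 − r(t))/G`, `r(t) = r0 e^(−t/θ)`, with the recorded
perpendicular channel divided by the G-factor (the same convention in
simulator and fitter). One subtlety: with T = 25 ns and θ ≈ 16 ns the
anisotropy term wraps appreciably between pulses (e^(−T/θ) ≈ 0.21), so the
difference signal is wrapped at the *combined* rate 1/τᵢ + 1/θ per
component — the exact per-pulse product — rather than multiplying the
wrapped total decay by r(t). The identity `par + 2·perp = 3·magic` (G = 1)
holds exactly either way and is asserted in the tests.

The global fit holds the decay parameters from the magic-angle fit fixed.
For a trial θ the two-channel model is linear in (u, v) = (I0, I0·r0), so
only θ is nonlinear: a bounded scalar search on log θ with an inner 2×2
weighted linear solve. r0 is clipped to [−0.2, 0.4] (re-solving the
amplitude at the bound, flagged as pinned); |r0| < 0.01 flags θ as
unidentifiable. The closed-form steady-state value
`r_ss = r0 Σ αᵢτᵢθ/(τᵢ+θ) / Σ αᵢτᵢ` provides the cross-check between
steady-state and time-resolved results; with r0 = 0.35 and the bound decay
set it evaluates to 0.322. r0 = 0.35 is an implementation default — chosen
once so this closed form lands within 1% of the measured steady-state
anisotropy of fully bound NADH (0.32) — not a measured quantity.

Steady-state intensities are integrated over the same analysis window as
lifetime fits, not the full period, so the steady-state and time-resolved
numbers describe the same photons.

## Environmental series and binding model

Temperature series: the mean-lifetime slope (default −8 ps/°C) is mapped
onto the components by scaling both lifetimes by a common factor with α₁
fixed; since τ_m is homogeneous of degree one in the lifetimes that factor
is exactly τ_m(target)/τ_m(reference) — the closed-form solution of the
one-dimensional root-finding problem this mapping poses. Intensity scales
linearly (default −2.2%/°C of the 25 °C value) and the steady-state
anisotropy slope (default −9.9×10⁻⁴/°C) is realised by adjusting r0 so the
closed-form r_ss follows the target line. Temperatures outside 25–45 °C
warn rather than fail. pH has no credible parametric model (the trends are
qualitative and non-monotonic), so pH series require an explicit
per-condition parameter table.

Binding: independent identical sites with total site concentration
S = sites·[LDH] give the quadratic solution for bound ligand B; the
concentration fraction is B/N and the intensity fraction reweights by the
bound/free brightness ratio (default 3.3, the LDH quantum-yield
enhancement). No literature Kd is baked in: Kd is a required user input,
and the Kd = 1.5 µM used with 12.5 µM NADH in tests and fixtures is a
synthetic choice that produces a well-spread titration curve, nothing
more. "Average slope over the data range" is ordinary least squares, with
a mean-of-pairwise-slopes variant exposed for sensitivity checks; the
theory-vs-fit titration comparison uses Spearman (rank) correlation
because the scientific claim is trend agreement, not pointwise agreement.

## What the simulator does and does not emulate

Emulated: periodic pulsed excitation with inter-pulse wrap, finite
Gaussian IRFs of the two detector widths, Poisson shot noise per bin,
polarized photoselection with a G-factor, brightness changes along
temperature and titration series, replicate structure via explicit seeds
(series replicates use seed + index).

Not emulated: detector afterpulsing, dead time, monochromator dispersion,
IRF drift between "days", optical scattering at high protein
concentration (the known cause of intensity anomalies in saturated
titrations), NADPH/FAD contributions, and the time-dependent degradation
of NADH at pH 4. Passing recovery tests therefore demonstrates the
correctness of the analysis chain under ideal shot-noise-limited
conditions; they do not bound the additional systematic errors these real
effects introduce.

## Problem sizes

Benchmarks and tests use 25 seeded replicates at 10⁶ photons per histogram
(the acceptance protocol), single histograms elsewhere, and 20 seeded runs
of six-point temperature series; each reconvolution fit takes tens of
milliseconds, so the full suite runs in well under a minute.

## Known limitations

- The background C is constrained non-negative; strongly over-subtracted
  control data can therefore pin C at zero (negative corrected bins
  themselves are retained and weighted by the original counts).
- The anisotropy fitter assumes a single rotational species; hindered
  rotation (r∞), associated anisotropy and multi-exponential rotors are out
  of scope.
- `fit_decay` with four free components is supported but poorly
  identifiable at realistic budgets; the constrained decomposition
  (`fit_bound_fraction`) is the intended four-component path.
- Reduced χ² is deflated below 1 by design at near-empty bins (see
  Fitting); compare fits by relative χ², not against 1.0.
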