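# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of `riskbn`.

## Experimental design generator

`build_design` lays out one participant's 32 avoidance manoeuvres.  The
(TTC, offset) condition table is fixed: offset 1.5 m crosses all four TTC
levels (frequency 0.125 each); offsets 1.0 and 0.5 m occur only with TTC 3.5
and 3.0 s (0.125 each).  Counts are exact (frequency × 32), trial order is a
seeded permutation, and the two nuisance factors (pedestrian walking
direction, avoidance side) are balanced 16/16 but carry no effect in the
generative model.  Trials are spaced 25 s apart on the session clock;
`t_level` (vehicle level with the pedestrian) is `t_start + TTC`, a
simplification of the vehicle kinematics that preserves everything the
analysis uses (ordering, spacing, and the anticipation geometry).

## Synthetic data

The generator defines the study conditions for every downstream test.  Two
paths produce data with shared ground truth.

**Indicator level** (`simulate_indicators`): the subjective assessment is
Gaussian within each condition cell.  Cell means (slider scale 0–1) follow a
three-tier pattern — 0.75 when TTC = 2.0 s (high risk), 0.45 when TTC = 2.5 s
or offset = 0.5 m (moderate), 0.25 when TTC ≥ 3 s and offset ≥ 1 m (low) —
with SD 0.12.  The SCR count indicator is Tweedie with log-link mean
`exp(−1.1 + 1.6·SA)`, dispersion φ = 2.5 and index ξ = 1.6; the amplitude
indicator is Tweedie with TTC-dependent mean (0.45/0.30/0.22/0.18 μS for
TTC 2.0/2.5/3.0/3.5).  The Tweedie parameters were set once so that the
marginal zero probability is about 0.45, the observed share of manoeuvres
without any electrodermal response; the exponential SA→SCR link is the
generative counterpart of the dependency the selection procedure is meant to
detect.  The area indicator iSA is the peak indicator scaled by the bump
geometry (base/2 = 3.5 s), so at the indicator level the two subjective
indicators are deterministically related; only the trace path gives them
independent numerical error.

**Trace level** (`simulate_traces`): the 20 Hz slider shows one triangular
bump per manoeuvre — linear rise over 4 s to a peak equal to the trial's SA
value exactly when the vehicle is level with the pedestrian, linear fall over
3 s — with breakpoints on the sampling grid, making the trapezoid integral of
the bump exact.  The 625 Hz conductance signal is a slowly drifting tonic
level (1 Hz random walk, 0.05 μS/min scale, interpolated), plus one Bateman
response per SCR event, plus white Gaussian noise (default SD 0.01 μS).
Event counts per manoeuvre are Poisson at the Tweedie rate implied by the
trial's SA; amplitudes are the compound-Poisson gamma jumps with the
TTC-dependent mean; onsets fall between 1 s before and 2.5 s after the level
moment, at least 1 s apart (the temporal resolution of response scoring —
closer pairs are not resolvable by any amplitude-threshold scorer and are
not generated).

What the generator does **not** emulate: habituation and drift of responding
over the session, participant-specific response amplitudes and anticipation
times, spontaneous (non-event-related) SCRs, slider hesitations and partial
returns to zero, and any effect of the nuisance factors.  Passing tests
therefore demonstrate correctness of the machinery under the stated
generative model, not robustness to every artefact of real recordings.

## EDA processing

Preprocessing resamples to 78 Hz (polyphase), applies a 1 s moving median
(spike removal) and a zero-phase 4th-order Butterworth low-pass at 1 Hz,
with reflection padding at the edges.

Tonic/phasic separation deconvolves the detrended signal against a Bateman
bi-exponential impulse response, `exp(−t/τ₂) − exp(−t/τ₁)` with
τ₁ = 0.75 s, τ₂ = 2.0 s (standard electrodermal values, configurable),
normalized to unit peak so that a driver impulse of mass *a* generates a
response of peak amplitude *a* μS.  The driver lives on a 10 Hz grid and is
estimated by non-negative least squares, chunk-wise (40 s chunks, 8 s
overlap margins) for linear scaling with session length; because the signal
is band-limited to 1 Hz the least-squares rows are decimated to 13 Hz with
no loss.  The tonic baseline is first estimated as a smoothed rolling 10th
percentile (20 s window) and then re-estimated from the deconvolution
residual in a second pass, so baseline bias is not absorbed into the driver.
Round-trip reconstruction error on synthetic inputs is below 1% of the
signal range.

Detection groups active driver nodes into events, splitting runs at interior
minima between local maxima at least 0.7 s apart — this is what separates
superimposed responses whose onsets differ by about a second.  An event's
amplitude is its total driver mass (default) or the peak of its
reconstructed response; events above 0.05 μS are retained.  Onset is the
mass-weighted node time: the deconvolution spreads an event's mass roughly
symmetrically around the true onset (the zero-phase filter smears the
response in both directions), and the centroid cancels that spread, landing
within ±0.2–0.3 s of truth.  Amplitude recovery through the
resample/median/low-pass/NNLS chain is accurate to about 2% — exact
equality is not attainable once the 1 Hz filter has attenuated part of the
response shape, which is why end-to-end tests assert counts and slider
maxima exactly but amplitudes only to that tolerance.

## Indicators

Slider windows are the zero-bounded interval around each level moment
(midpoint fallback with a warning when the slider has not returned to zero).
mSA is the window maximum; iSA the trapezoidal integral, exact for
piecewise-linear bumps with grid-aligned breakpoints and O(Δt²) otherwise.
The participant's anticipation delay `w_start` is the mean over manoeuvres of
(level moment − first strictly positive slider sample); manoeuvres with no
response have no defined delay and are excluded from the mean ("strictly
positive" uses 1e−6 of full scale against quantization noise).  SCR events
are attributed to a manoeuvre when their onset lies in
`[t_level − w_start, t_level + w_end)` with `w_end` = 3 s; the window is
closed on the left and open on the right (a convention — the boundary cases
are measure-zero).  nSCR counts the events, mSCR is the maximum amplitude
among them, with (0, 0) when none fall inside.

## Transforms

mSA^½ and iSA^⅓ correct the right skew of the subjective indicators before
per-participant centring and unit-SD scaling (unbiased, n−1).  A useful exact
identity: per-participant z-scores of P participants × n values have pooled
mean 0 and pooled unbiased SD √(P(n−1)/(Pn−1)) regardless of the data —
0.98506 for 20 × 32 — which the tests exploit.  SCR indicators are scaled
but never centred: centring would move the exact zeros that give the Tweedie
model its point mass.  Skewness is the adjusted Fisher–Pearson statistic;
normality is checked by Shapiro–Wilk.

## Tweedie engine

The density for y > 0 is the compound-Poisson series over the latent count,
evaluated in log space with `logsumexp`; the summand peaks near
j* = y^(2−ξ)/(φ(2−ξ)) and the j-range doubles until boundary terms are below
1e−12 of the peak.  The atom at zero is exp(−μ^(2−ξ)/(φ(2−ξ))) in closed
form.  Sampling uses the constructive definition (Poisson count, gamma sum,
collapsed to a single gamma with N-fold shape).

Regression fitting: coefficients by IRLS for the log link (weights
μ^(2−ξ), independent of φ), then φ by maximizing the *series*
log-likelihood at fixed ξ (bounded search in log φ around the Pearson
moment estimate), then ξ by profile likelihood over the grid 1.05…1.95
(step 0.1) refined by bounded minimization between the best point's
neighbours.  Using the true likelihood rather than quasi-likelihood keeps
node log-likelihoods valid inputs to BIC.  Coefficient standard errors come
from the weighted information matrix φ⁻¹XᵀWX.  The free-parameter count for
BIC is `len(beta) + 2` (φ and ξ both estimated); ξ is profiled per node.
The engine deliberately covers only 1 < ξ < 2 (no Gaussian, Poisson or
stable branches).

## Network scoring

Factor root nodes use the design frequencies as fixed parameters: zero free
parameters, and a data-dependent constant log-likelihood that cancels in
comparisons but keeps totals absolute.  A Gaussian node with discrete
parents gets a mean and an (MLE) SD per observed cell (2 parameters per
cell; the four untested factor combinations never appear and are never
imputed); with a continuous parent it gets per-cell intercepts, a common
slope and a common SD (no interaction — not identifiable at this scale).  A
Tweedie node gets log-link cell means with shared (φ, ξ) — per-cell
dispersion is not identifiable at 80 observations per cell — plus a linear
term on SA when that edge is present.  Node BICs use n = number of rows and
sum to the network BIC exactly, which the tests verify against a direct
joint-likelihood computation.  All 48 structures are scored exhaustively
(node fits are cached per parent set, so a full scoring costs 8 Tweedie and
8 Gaussian fits); ranking grades consecutive BIC gaps 2/6/10 and flags
everything within 2 of the best as indistinguishable, with exact ties broken
by structure serialization for determinism.

## Condition clustering

Every set partition of the 8 conditions (enumerated by restricted growth
strings; Bell(8) = 4140) is scored as a Gaussian model with one mean per
block and a single pooled SD (`n_blocks + 1` parameters; per-block SDs
behind a flag).  Selection applies the grades of evidence to the exhaustive
search: partitions within 2 BIC of the minimum are indistinguishable, and
among them the most parsimonious is retained.  This guard matters: the
minimum over 4140 correlated models inflates the apparent BIC gain of
spurious splits, and without it the null (all conditions identical,
80 observations each) keeps a spurious extra block in roughly 40% of
replicates; with it, the single-block model is retained in ~86% — the
residual is the irreducible selection effect, a known limitation of
information-criterion search over large discrete model spaces.  Winning
blocks are labelled low/mid/high by ascending mean.

## Pipeline and problem sizes

The default pipeline simulates 20 participants × 32 trials at the indicator
level (640 rows), scores the 48 structures for each of the four indicator
pairs, and clusters both subjective indicators; trace-level simulation and
the full signal path are behind `with_traces` (about 10 s per participant,
dominated by the deconvolution).  Recovery simulations in the tests use the
study scale throughout: n = 640 rows per replicate, 100 replicates for
parameter recovery, 50 for structure recovery.  Detector benchmarks use
complete 32-trial sessions (~810 s of 625 Hz signal each).  Outputs carry
the configuration hash and seed; reruns with the same configuration are
byte-identical.

## Known limitations

* The deconvolution is a fixed-kernel NNLS method: it does not optimize the
  impulse-response time constants per participant, and amplitude recovery is
  ~2%, not exact.
* mSCR under the default generator depends on TTC only weakly relative to
  the Tweedie noise (φ = 2.5), so the BIC search — conservative by design —
  often prefers the parentless SCR node for the amplitude pairs, as in the
  worked example.  The count pairs carry the SA link and are the ones that
  decide the independence question.
* At the indicator level, mSA and iSA are proportional by construction;
  conclusions about their *relative* sensitivity require the trace path.
* Tweedie fitting assumes at least one positive response per fitted cell
  configuration; degenerate all-zero cells raise an error rather than being
  imputed.
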