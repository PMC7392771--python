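# Methods

## Measurement model

Amperometry at +0.7 V vs Ag/AgCl oxidizes H₂O₂ at a platinum microwire,
two electrons per molecule, giving a current proportional to the local
H₂O₂ production rate. Three co-terminating 127-µm wires form one sensor:

- **GLU channel** (GOx): GLU + O₂ + H₂O → α-ketoglutarate + NH₃ + H₂O₂.
  Current is linear in [GLU] up to the linear range, slope SS_GLU (pA/µM).
- **GABA channel** (GOx + GABASE): GABASE transaminates GABA using the
  α-ketoglutarate generated by the co-immobilized GOx, ultimately
  yielding additional H₂O₂. Its current therefore contains a GLU
  crosstalk term (slope SS_GLU.in.GABA at zero GABA) plus a
  GABA-attributable part whose size depends on the ambient GLU supplying
  the α-keto shuttle. The calibration for this coupled response is a
  *family of lines*: current density versus [GLU], one line per GABA
  level. With no GLU there is no shuttle and the GABA channel is blind to
  GABA — the inversion flags such samples rather than guessing.
- **Sentinel channel** (no enzymes, same permselective coating): sees
  only directly electroactive interferents (ascorbic-acid-like), used for
  background subtraction.

We model all of this *phenomenologically* through effective
sensitivities; enzyme-layer reaction–diffusion kinetics, film aging and
electrode impedance are out of scope.

## Forward simulator (`synthetic`)

The generator renders the structure the analysis assumes, with known
ground truth and a mandatory seed (identical seed ⇒ bit-identical trace):

- **Linearity and saturation.** Within the linear ranges (0–300 µM GLU,
  0–500 µM GABA) the response is exactly linear. Above the range
  endpoint L the effective concentration follows
  `L + K·(1 − exp(−(C − L)/K))` — smooth, concave, C¹ at L, with
  asymptote L + K. The saturation constants (K = 80 µM for GLU, 150 µM
  for GABA) are chosen so the response visibly flattens just above the
  linear range, i.e. so that a synthetic calibration curve yields its
  nominal linear range under the pipeline's own prefix-R² rule (below).
  The GABA-channel line family is *not* additionally saturated in GABA:
  the anchor slopes themselves already grow sub-linearly with GABA level,
  and the top anchor clamps the response.
- **Line family.** Anchor slopes 14, 28, 55, 89, 146 nA·µM⁻¹·cm⁻² at 50,
  100, 300, 500, 1000 µM GABA, intercepts 0 (the simplest model
  consistent with a through-origin shuttle response); slope and intercept
  are interpolated piecewise-linearly in GABA level, with a zero line
  anchored at GABA = 0.
- **Kinetics.** A causal first-order tracking filter,
  dy/dt = (x − y)/τ, with τ_rise while the drive exceeds the state and
  τ_decay while it relaxes; τ = 0 means instantaneous (used by the
  idealised recovery checks). Defaults 0.8 s / 2.0 s for stirred-bath
  sessions; the *unstirred* preset multiplies τ_rise by a factor
  constrained to [7, 10] (default 8.5), reproducing the 7–10× slower
  diffusion-limited rise seen without convective transport. For in vivo
  sessions we use 50 ms time constants: sub-second events (FDHM down to
  ~70 ms) are observable in such recordings, implying much faster
  equilibration with the sensor apposed to active synapses.
- **Nuisances.** White Gaussian noise per sample and channel (the noise
  spectrum is otherwise uncharacterised), optional common-mode linear
  drift, half-sine interferent transients applied with equal gain to all
  channels (sentinel gain configurable, default 1 so sentinel
  subtraction can cancel them exactly), and square stimulation-artifact
  transients on the enzymatic channels (gain 0.3 on the sentinel).
- **Behavioural scripts.** Interictal segments place synchronized
  negative dips (default 0.44 s at 0.13 Hz, GLU 18→4 µM, GABA 15→2 µM);
  sleep ramps GABA up ~31% then plateaus with GLU flat; wake drops GABA
  ~32%; walking/grooming add band-limited antiphase fluctuations;
  seizures add large synchronous swings. The sleep/wake session GABA
  baseline (20.5 µM) is set so that the ±31/32% swings around the 18-µM
  GLU baseline produce per-state E/I levels of roughly 0.67 (sleep) and
  1.3 (wake). In vivo baseline currents and noise (2 pA) are free
  parameters of the generator, chosen once.

What the generator does **not** emulate: 1/f and mains noise, electrode
drift nonlinearity, movement artifacts, enzyme-layer degradation over
sessions, and any biological variability beyond lognormal release jitter.
Passing tests therefore demonstrate correctness of the analysis chain
under its stated assumptions, not robustness to every pathology of real
recordings.

## Calibration (`calibration`)

- **Plateaus**: mean over a window (default 30 s) that ends 2 s before
  the next addition, after a 20-s settle; the bath protocol shows
  minutes-scale steps, so these defaults leave wide margins and are
  configurable.
- **Sensitivity**: OLS slope of plateau current vs concentration over
  in-range points; an intercept is fitted (baseline offset) but the
  sensitivity is the slope alone. Division by the wire area converts to
  current density.
- **Linear range**: the largest ascending-concentration prefix whose OLS
  fit keeps R² ≥ 0.98 (matching the fit quality reported for such
  calibrations); if even the minimal 3-point prefix fails, that prefix is
  returned flagged. Prefix-R² is forgiving of mild curvature — with a
  gentle saturation the rule can keep a partially saturated point — which
  is why the simulator's saturation is sharp (see above).
- **LOD**: 3·sd over the 10 consecutive baseline samples immediately
  preceding the first addition, divided by the slope.
- **Selectivity**: analyte/interferent sensitivity ratio; an interferent
  slope of zero returns infinity with a flag.
- **Family fit**: one OLS line per GABA level; slopes must increase
  strictly with level or the calibration is rejected.
- Group utilities (one-way ANOVA, two-tailed t) wrap scipy behind this
  module's surface and are verified against textbook formulas.

## Deconvolution (`deconvolution`)

Sentinel subtraction, division by SS_GLU, crosstalk removal and family
inversion are applied sample-wise to whole traces *and* scalar-wise to
peak currents. The peak-level path is the reference: peak currents are
far less noise-sensitive, because the sample-wise GABA inversion divides
by the family-line spacing, which shrinks with [GLU] — as [GLU] → 0 the
GABA estimate is noise-amplified and eventually undefined. Per-sample
flags record this: `clipped_negative` (negatives clipped to 0),
`out_of_linear_range`, `family_extrapolated` (above the top line, or
family uninformative at zero GLU). Inversion is piecewise-linear in GABA
level against the densities the family predicts at the measured [GLU],
interpolating toward zero below the lowest line and clamping at the top.

A known discrepancy: the original graphical worked example for the
family inversion (12,500 nA/cm² at 130 µM GLU read as ≈481 µM GABA) is
not reproducible from the printed anchor slopes under through-origin
interpolation, which places that point differently; the figure's
intercepts were never tabulated. We document rather than chase it.

No detrending beyond sentinel subtraction is applied.

## Peak analysis (`peaks`)

Baseline = mean of the last 10 s of each response segment (responses
return to rest before the next stimulation). Thresholds at 10/50/90% of
the baseline-subtracted maximum; crossing times are linearly interpolated
between the bracketing samples, taking the nearest crossings flanking the
global maximum (multimodal segments use the global max). T_R = 10→90%
rise interval, T_D = 90→10% decay interval, FDHM = between the 50%
crossings. Interpolation matters: at 1 kHz sampling, durations down to
70 ms would otherwise be quantized to ~1.4% steps. A missing downward
crossing flags `no_return_to_baseline`.

QC: discard when amplitude < 2× the pre-stimulus noise SD (SD over the
same baseline window, aligning the noise convention with the LOD
baseline) or when the sentinel peak exceeds the raw GLU peak; slice-level
health uses the mean of the first three control-pulse responses, with
"80% or less" read as ≤ (boundary inclusive) and discard sticky from the
first failure.

Artifact handling: samples within a blank window after each stimulation
pulse (default 1.2× the train duration when taken as one window; the
drivers use 30 ms per pulse) are masked as missing; kinetics interpolate
across the gaps. Interictal-like spikes are contiguous excursions beyond
a threshold fraction (default 0.3) of a slowly varying local baseline
(per-window medians, interpolated), with durations measured
departure-to-return; traces are first smoothed over ~25 ms because of
the low-GLU noise amplification above; events open at the segment end are
excluded and counted. A zero-crossing fluctuation counter is provided for
exploratory use without claiming parity with any particular published
counting convention.

## E/I analysis (`ei`)

E/I is computed per response and then averaged (the default), not as the
ratio of group means — group E/I values published for such experiments
are inconsistent with the ratios of the published mean concentrations,
which identifies per-response averaging; both modes are exposed.
Dispersion is SEM for slice condition summaries and SD for in vivo epoch
summaries, tagged explicitly. The two-group comparison is the
independent two-sided Wilcoxon rank-sum test: full enumeration of all
C(n, n_a) rank splits (midranks under ties) for combined n ≤ 16,
otherwise the tie-corrected, continuity-corrected normal approximation;
α = 0.05; pairwise tests are reported unadjusted (a Holm flag exists but
is off by default). Sleep/wake episode E/I uses the episode-mean GLU
against the sleep GABA maximum or wake GABA minimum, read from a 5-s
smoothed trace since these dynamics evolve over minutes.

## Numerical choices and problem sizes

- Uniform sampling enforced to 1e-6 relative; trace CSV round-trips to
  better than 1e-9.
- Moving averages shrink their window at boundaries (no NaN padding);
  means are conserved away from edges.
- Degenerate inversion inputs: negative densities clip to 0 (flagged);
  zero-GLU samples return 0 µM GABA with the extrapolation flag.
- The simulated sessions in the tests and drivers run at 50–1000 Hz and
  tens to hundreds of seconds — small enough for the whole suite and the
  acceptance run to finish in seconds while exercising every code path
  at realistic SNR.
- Monte-Carlo checks (plateau accuracy, family-slope coverage, noisy
  peak recovery) use 100 seeded replicates; the family-coverage check
  uses 20 calibration points per line so that 3·SEM coverage (a t-based
  interval) genuinely exceeds its claimed rate.

## Known limitations

- The GABA channel cannot report GABA when GLU is absent; this is a
  property of the chemistry, faithfully reproduced, and the reason the
  peak-level conversion is preferred for quantitative claims.
- The linear-range rule is a heuristic; with gently saturating sensors
  it can overestimate the range (flagged in the diagnostics when even
  the minimal prefix fails, but not when curvature is mild).
- Epoch labels are consumed as given; no behavioural scoring is inferred
  from the signals.
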