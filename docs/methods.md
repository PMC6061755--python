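# Methods

This note documents the models behind `botanicad`, the parameters that
matter, what the synthetic-data generator does and does not emulate,
and the numerical choices made where the design was genuinely open.

## Relative quantitation by charged aerosol detection

The quantitation model is deliberately simple: CAD response is treated
as proportional to analyte mass, so the share of total detected signal
is the share of extract mass,

percentᵢ = 100 · areaᵢ / Σⱼ areaⱼ,

with the sum running over *detected peaks only*.  The broad unresolved
background hump seen in tannin-rich extracts is excluded from the total
by construction (it is absorbed into the baseline); a config hook
(`include_hump_in_total`) exists for sensitivity analysis but no
solvent-response correction model is implemented — inverse-gradient
hardware handles that upstream of the data and has no computational
counterpart here.  CAD accuracy under this model is expected to be
within about a factor of two, which is sufficient for the conservative
TTC use of the numbers.

## Baseline estimation

Asymmetric least squares (a Whittaker smoother with asymmetric
weights): points above the current baseline get weight `p` (default
1e-3), points below `1-p`, with a second-difference penalty `lam`
(default 1e9).  At 5–10 Hz sampling this follows humps ~10 min wide
while ignoring UHPLC peaks a few seconds wide.  Two numerical details
matter:

- the solve runs on median-centered data, so a flat trace returns its
  offset exactly instead of inheriting the solver's conditioning error;
- plain ALS pins the baseline near a low quantile of the noise (the
  weight asymmetry makes it hug the lower envelope), which would shift
  residuals by ~+2.5 σ and inflate every S/N estimate.  The estimate is
  therefore re-centered on the mode of the residual distribution
  (shortest interval containing 10 % of residuals), which is robust
  both to sparse one-sided peaks and to peak-dense noiseless traces.

## Peak detection and the reporting floor

Detection runs on the baseline-subtracted signal: candidates are local
maxima of a lightly smoothed copy (Savitzky–Golay, window set from the
median candidate width so noise cannot split one peak into several),
the apex is then refined to the maximum raw sample within half a peak
width — the convention chromatography data systems use for "peak
height".  Noise is 1.4826 × MAD of residuals in peak-free regions;
snr = apex height / noise.  Because the apex is a local maximum of the
raw signal, measured S/N at the detection boundary is biased slightly
high, which is why a peak constructed at exactly S/N 3 is detected
reliably rather than half the time.

Bounds lie at the valley shared with an adjacent detected peak
(fused CAD peaks are split at the minimum, never deconvolved) or at
the baseline re-crossing, extended to at least ±4 estimated sigma so
tail truncation does not bias small-peak areas; integration is
trapezoidal on the raw baseline-subtracted signal.  The 0.05 %
relative-area reporting floor is applied in a second pass once the
total detected signal is known, with a 1 % relative guard so a
constituent sitting exactly at the floor is reported rather than
censored by finite integration bounds.

The detection-floor experiment (`detection_floor_experiment`) measures
observability: minor peaks on a logarithmic relative-area ladder, noise
fixed so the 0.05 % rung sits at apex S/N = 3.  The S/N gate runs at
its default (3); the reporting floor is off inside the experiment
because applying a 0.05 % cutoff while measuring whether 0.05 % peaks
are detectable censors the measurement at its own value.

## Exact-mass chemistry

Isotope masses and abundances are a pinned transcription of the
NIST/CODATA compilation (AME2020 masses, 2021 abundance evaluation),
shipped in `elements.py` and overridable from YAML; electron mass is
included in all charged-species m/z (0.55 mDa matters at ppm-level
accuracy).  Isotope envelopes are computed by exact convolution over
element isotope distributions, aggregated at nucleon resolution
(A, A+1, A+2, …) with abundance-weighted centroid masses — aggregation
during convolution is exact because nucleon offsets are additive.
Fine structure is never exposed publicly; the detectors being emulated
resolve A/A+1/A+2 but not fine structure.

DBE uses the standard valence convention: halogens count as H,
phosphorus as N, divalent O/S contribute zero; other elements
contribute zero with a warning.

## Formula assignment and the 0–100 score

Candidate enumeration is an iterative nested counting loop over the
non-hydrogen elements (heaviest first) with early mass pruning; the
hydrogen count is solved from the residual mass, so runtime is linear
in the pruned C×N×O grid.  Chemical filters: DBE ≥ 0 and integer for
even-electron ions, H ≤ 2C + N + 2, and the nitrogen parity rule for
singly charged ions (toggleable).  Default bounds C 0–100, H 0–150,
N 0–6, O 0–40 suit CHNO-dominated plant chemistry; default tolerance
5 ppm.

The score is a weighted Gaussian-kernel composite,

score = 100 · (w_m·S_mass + w_a·S_abund + w_s·S_spacing),

with S_mass = exp(−½(Δppm/σ_ppm)²) on the A peak and S_abund/S_spacing
mean-squared kernels over the A+1…A+K relative abundances (A = 100) and
adjacent spacings (K = 2 by default — the evidence the emulated
workflow actually inspects).  A theoretical peak with no observed
counterpart contributes its worst-case deviation capped at 3 σ, so thin
envelopes degrade gracefully instead of failing.  Defaults:
w = (0.4, 0.4, 0.2), σ_ppm = 5, σ_abund = 3 relative-abundance points,
σ_spacing = 0.002 Da, confident at ≥ 90.  σ_abund is matched to the
few-point precision of measured A+1/A ratios; a much wider kernel
(e.g. 10 points) washes out exactly the information that separates the
ubiquitous near-isobar one +C +4N −4H −4O swap away (+1.34 mDa), and
formula recovery degrades from ~97 % to ~90 % under the conditions
below.  Ties rank by |ppm|, then fewer heteroatoms, then Hill string.
A genuine ambiguity worth knowing about: [M+H]⁺ of CₓH_yN O_z and
[M+NH₄]⁺ of the N-free analogue are the *same ion formula* and cannot
be separated by any envelope; the heteroatom tie-break then prefers
the N-free reading.

Envelope noise in `simulate_envelope` is a per-envelope calibration
shift drawn uniformly within the stated ppm bound — on a TOF analyzer
the peaks of one envelope share the spectrum's calibration state, so
their mass errors are coherent — plus uniform bounded noise on each
A+k/A ratio.  Under 2 ppm / 5 % conditions the generating formula ranks
first in ≈97 % of random CHNO compositions up to C50.

## MS feature detection and adduct grouping

Centroids are linked across adjacent scans (greedy nearest-m/z within
ppm tolerance); a feature needs ≥ 3 consecutive scans, far below peak
width at 5 Hz.  Co-eluting traces spaced 1.00336/z Da merge into one
feature (z ≤ 2 by default); co-elution is judged on intensity-weighted
centroid times, which are far more stable under scan-to-scan intensity
noise than apex scans.  Adduct grouping inverts the adduct arithmetic:
features whose implied neutral masses agree within tolerance and whose
apexes agree within 0.05 min merge, each feature receiving exactly one
adduct by pairwise vote (ties → smallest neutral-mass disagreement);
unexplained features become singleton groups under [M+H]⁺/[M−H]⁻.
In-source fragments are not modeled.

## Fusion and the constituent report

Detector pairs are related by a constant transit-time offset
(median of matched apex differences; antisymmetric by construction).
A group is assigned to the CAD peak whose bounds ± 0.1 min contain its
offset-corrected apex; overlaps resolve to the nearest apex.  CAD area
is *not* apportioned among coeluting analytes — they are reported
jointly under one peak number, because MS response is too
structure-dependent to weight a mass-proportional signal (an optional
EIC-proportional split exists behind a flag, labelled non-quantitative).
Groups below 5 % of the peak's top group count as low-level extra
signals, flagged but not counted as analytes.  Confidence tiers:
standard match (formula + RT against a reference table) > proposed
(confident score plus external annotation text) > formula-only >
no-MS-signal.  UV evidence is recorded as a boolean only; no spectral
similarity metric is defined for it.

For the unknown-signal statistics, "unidentified" means no proposed
name and no standard match — a bare molecular formula does not identify
a constituent (config can flip this interpretation; the default mirrors
how unknowns that still carry formulas are counted in this kind of
characterization).

## Synthetic extracts and the packaged table

The generator renders constituents as exponentially modified Gaussians
(so USP metrics are non-trivial) with areas proportional to mass
fraction, on a Gaussian hump with additive noise; spectra are generated
centroided directly, with per-centroid ppm and intensity jitter.
Default conditions: 10 Hz CAD / 5 Hz MS sampling, total CAD area 1000
units·min with noise σ = 1 — placing a 0.05 %-of-total peak of default
width near S/N 3, the reporting-floor regime the workflow is designed
around — hump amplitude 50 at σ = 10 min, 2 ppm / 5 % MS jitter.

The packaged 83-peak table carries names, CAS numbers, formulas, adduct
annotations and confidence tiers, with coeluting analytes as repeated
peak numbers.  Two columns are synthetic and labelled as such: the
retention-time grid (the published table prints none; the fixture
spreads peaks evenly over the 125-min window in elution order) and the
per-peak composition (`synthetic_ginkgo_composition`), constructed to
the aggregate profile the study class reports — unidentified peaks
carry ≈10 % of total signal with no single one above 1.2 % and the
smallest at the 0.05 % floor, identified signal weighted so flavonoid
glycosides exceed 24 % and terpene trilactones 6 % of the total.  The
supplementary per-peak percentages themselves are not part of the
package; the `esm_percent` column is null.

What passing tests on synthetic data do **not** show: real CAD
response is only approximately mass-proportional and varies with
solvent composition; real electrospray produces in-source fragments,
background ions and intensity-dependent mass error; real extracts
contain far more than the simulated analytes below the floor.  The
generator emulates none of these, so end-to-end recovery results bound
algorithmic, not instrumental, error.

## Known limitations

- Fused CAD peaks are split at the valley, never deconvolved; relative
  amounts of coeluters are reported jointly.
- No MS/MS interpretation: identification beyond molecular formula
  requires external annotation input.
- Charge states above 2 are not searched by default.
- The mode-based baseline re-centering assumes peaks plus hump do not
  occupy essentially the whole trace at high amplitude everywhere; a
  trace that is one unresolved mass of overlapping peaks will bias the
  baseline upward.
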