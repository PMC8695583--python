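# Methods

This note documents the models behind `spacerscreen`: what the synthetic
screen generator emulates, the statistics the pipeline computes, the
numerical choices made where the design was genuinely open, and what
passing tests do and do not establish about real data.

## Biological setting

A bacterial sigma70 promoter consists of the −35 hexamer (consensus
TTGACA), a spacer of flexible length, and the −10 hexamer (consensus
TATAAT). The spacer is written 5'→3' with position 1 adjacent to the −35
element; a 5'-TG-3' dinucleotide at positions (L−2, L−1) — one base
upstream of the −10, the TGn-TATAAT geometry — is the classical
"extended −10" motif that stabilizes RNAP binding. Native spacers run
15–21 bp with 17 bp optimal; synthetic libraries extend this to 12–23 bp.
Negative DNA supercoiling (superhelical density σ) assists promoter
melting; σ is most negative in exponential phase and relaxes toward
stationary phase, and sub-lethal gyrase inhibition (novobiocin) shifts it
further toward relaxation without a growth defect.

## Sequence features

* **GC content, TG counts, consensus mismatches** are literal counts;
  degenerate IUPAC bases are rejected rather than expanded, because
  library members are resolved sequences after Sanger sequencing.
* **Melting energies** use the unified nearest-neighbor ΔG°37 parameter
  set for Watson–Crick dimer duplexes (SantaLucia, PNAS 95:1460, 1998),
  a 10-entry table stored in `sequence_features.NN_DG37`. The sign is
  flipped to a stability-to-melt convention: larger = harder to melt.
  Free energy (not enthalpy) is used; at 37 °C it is the thermodynamically
  relevant quantity for strand separation. Reverse-complement symmetry of
  the table makes the profile strand-invariant, which the suite
  property-tests.
* **Logos** report column base frequencies and information content
  ic = 2 − H (bits), uncorrected by default; a Miller–Madow small-sample
  correction is available behind a flag but off, matching the common
  uncorrected presentation of library logos.

## The synthetic screen generator

The generator is first-class, tested code; its defaults ARE the study
conditions, fixed once and not tuned per analysis.

* **Library**: i.i.d. uniform-ACGT spacers, 12 lengths (12–23 bp),
  96 picked colonies per length plus 96 random-promoter controls;
  Golden Gate oligos follow the fixed BsaI scheme
  `GGTCTCGGACA(N)nTATACGAGACCGTGTCTATCAC` with GACA/TATA overhangs, and
  spacers containing an internal BsaI site are rejected.
* **Strength**: `base_curve[L] × exp(ε) × tg_damp^(#TG) × tandem_damp^(tandem≥2)`
  with ε ~ N(0, 0.46). The length curve peaks at 17 bp (1000 a.u.), with
  16/18 bp close behind (870/900), a 15–19 bp high plateau, a moderate
  long-spacer shelf and a steep drop below 15 bp; controls sit at a
  background of 3 a.u. The lognormal spread is sized so the max/min ratio
  among ~96 clones of one length is about ten-fold. Each TG dinucleotide
  damps strength ×0.60 and a tandem TG·TG ending at the extended −10
  damps a further ×0.45 — TG motifs tighten RNAP binding and brake the
  promoter.
* **Selection**: a phenomenological toxicity cull — clones above 600 a.u.
  die with probability 0.9. The mechanism of toxicity is deliberately not
  modeled (it is unresolved experimentally); the cull reproduces its two
  observable consequences: markedly lower colony yield for
  optimally-spaced libraries and enrichment of TG-damped (weaker) clones
  among survivors.
* **Supercoiling**: cellular σ interpolates from −0.060 (exponential) to
  −0.035 (stationary) with growth phase (Δσ = 0.025); 17 µg/mL novobiocin
  adds a relaxation shift of +0.00195 in exponential and +0.00156 in
  stationary phase, dose-linear below that. Each clone has an intrinsic
  optimum σ_opt = −0.034 − 0.07·(GC − 0.5) + N(0, 0.006) — GC-rich
  spacers need more negative supercoiling to melt — and instantaneous
  activity is Gaussian in σ around it (width 0.015).
* **Strength–sensitivity coupling**: gyrase inhibition limits removal of
  positive supercoils downstream of elongating RNAP, so strong promoters
  suffer under treatment irrespective of their promoter-level σ response.
  This is modeled as `(1 + S)^(−0.04·c/17)` — a power law, i.e. linear in
  log-strength — kept separate from the σ response so the screen's bias
  correction has something real to remove. The log-linear form was chosen
  deliberately: the bias-correction step regresses log2 ratio on log10
  strength, and a generator whose elongation artifact is log-linear makes
  that regression well-specified. (An exponential-in-S form would leave
  curvature that no straight-line correction can remove; nothing in the
  source measurements distinguishes the two.)
* **Readout**: logistic growth (od0 0.012, K 1.2, r 0.9 h⁻¹, 15 h at
  15 min resolution); rfu(t) = cumulative per-cell production × OD(t) +
  blank + N(0, 15); OD measurements add the medium blank (0.04) and
  N(0, 0.003). Endpoint screens read the last timepoint of mirrored
  plates (8 clones per length per 96-well plate).
* **EMSA**: θ = cⁿ/(Kdⁿ + cⁿ) + N(0, noise_sd) clipped to [0,1]. The
  default Hill coefficient n = 2 is a simulator choice — the source
  measurements report only Kd values (358 ± 19 nM for the weakest 17 bp
  clone, 817 ± 4 nM for the strongest), not n.

Free parameters with no stated value (σ_ref, opt_slope, jitter, width,
elong_penalty, damping factors) were calibrated once against the published
regime — treated/untreated ratios spanning roughly a 50% increase to a
2-fold decrease, a strength–sensitivity Spearman near −0.6, a monotone
GC-bin trend with AT-rich up-regulation, and TG enrichment among weak
survivors — and then frozen.

All randomness flows from a single seed through named CRC32-keyed
substreams (`substream(seed, name)`), so any module's draw is reproducible
in isolation.

## Screen statistics

* **Normalization**: (RFU − blank_rfu)/(OD − blank_od); wells with
  blank-corrected OD ≤ 0.05 are flagged invalid, never silently dropped.
* **Extreme groups**: bottom-48/top-48 by untreated RFU/OD600 with ties
  broken by clone id, making the partition order-invariant.
* **Motif enrichment**: per-position TG frequencies and extended −10
  frequency with 95% Wilson intervals; logos via the sequence module.
* **Melting comparison**: per-step Welch tests with Benjamini–Hochberg
  adjustment across positions (the multiple-testing method is a package
  choice; only non-significance was reported for weak vs strong groups).
* **Sensitivity**: ratio = treated/untreated RFU/OD600; neutral at 1.
* **Bias correction**: OLS of log2(ratio) on log10(strength);
  corrected_ratio = 2^residual. The correction is multiplicative so
  neutral stays at 1 and the geometric mean of corrected ratios is ~1 by
  construction. Requires ≥10 records spanning >1 decade of strength.
* **GC bins**: default 5 equal-width bins on [0.2, 0.8] (the bin edges
  are a package choice); up = corrected_ratio > 1, down = < 1, exact 1 in
  neither; a zero denominator reports the Haldane-adjusted
  (n_up+0.5)/(n_down+0.5), flagged; empty bins report NaN. Records outside
  the configured edges are excluded by the caller (extreme-GC spacers of
  short libraries fall outside [0.2, 0.8]).
* **Timing preference**: the OD600 = 0.3 crossing time is linearly
  interpolated between bracketing timepoints; expo_fraction =
  blank-corrected RFU at the crossing / at the last timepoint. This reads
  "amount of expression in exponential phase" as the signal at the
  crossing, matching a ratio-of-two-timepoints definition; a cumulative
  production reading would be an alternative but is not implemented.
  With measurement noise the fraction can fall marginally outside [0, 1]
  for near-background wells.

## EMSA fitting

Per-replicate nonlinear least squares of the Hill equation; initialization
Kd at the concentration nearest half-saturation and n = 1; bounds
Kd ∈ (0, 100 × max conc], n ∈ (0, 10]. Replicates with a flat
fraction-bound profile (range < 0.05) or a non-convergent/boundary fit are
flagged and excluded. The reported Kd is the mean of per-replicate fits
and its SE the replicate-level standard error — matching an
error-bars-over-replicates presentation; a pooled fit is available behind
a flag. Concentrations are nM throughout; unit-less files are rejected.

## Native-promoter expression

Counts are divided by the per-timepoint total and the CDS length, then by
the gene mean, so the all-gene average is exactly 1 at every timepoint and
a value of 10 means ten-fold the average gene. Promoter strength is the
maximum over timepoints. The sigma70 consensus filter keeps promoters with
≤3 mismatches summed over both hexamers (the summed reading of "3 bases
deviation"; a per-element variant is available via a flag). Genes with
zero counts everywhere keep relative expression 0 and are retained.

## Problem sizes

The default screen is the full study design (12 × 96 clones + 96
controls, two conditions, 61 timepoints); multi-seed property checks use
10–20 independent screens, and EMSA analyses use 4 replicates × 12
concentrations. These sizes run in seconds because the kinetics are
vectorized across clones.

## What the synthetic data do not capture

Plate/batch effects beyond the mirrored layout, evaporation, growth
differences between clones or doses (all clones share one growth curve,
consistent with the no-growth-defect observation), reporter maturation
and dilution kinetics, copy-number variation, read-mapping noise on the
native side, and any mechanistic account of the toxicity. Passing the
suite shows the pipeline recovers the generator's couplings at realistic
sizes and noise — not that the biological effect sizes are as simulated.

## Known limitations

* The bias correction assumes a log-linear strength artifact; on data
  with a different elongation-coupling shape the residuals would retain
  curvature.
* GC-bin ratios are count-based and noisy in sparse bins; the Haldane
  adjustment is flagged rather than hidden.
* The Hill fitter reports replicate-level SE, which conflates titration
  noise with replicate-to-replicate variation.
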