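# spacerscreen

Analysis pipeline for bacterial sigma70 promoter **spacer** screens: how
the DNA between the −35 and −10 hexamers sets promoter strength, RNAP
binding, DNA-supercoiling sensitivity and expression timing.

The package is aimed at groups running plasmid-born random-spacer reporter
libraries (plate-reader OD600/fluorescence screens, with and without mild
gyrase inhibition) and EMSA binding assays, and at anyone who wants a
fully synthetic, mechanistically interpretable test bed for such screens.

## What it computes

* **Sequence features** — GC content, TG-dinucleotide counts, the
  extended −10 motif (5'-TG-3' at spacer positions L−2/L−1, TGn-TATAAT
  geometry) and tandem TG runs, mismatches to the TTGACA/TATAAT
  consensus, nearest-neighbor melting-energy profiles (unified ΔG°37
  set), and sequence logos with per-position information content
  ic = 2 − H bits.
* **Synthetic screens** — a generative model of the whole experiment:
  random 12–23 bp spacer libraries behind a consensus promoter, toxicity
  selection against the strongest clones, logistic growth with a
  growth-phase σ trajectory (−0.060 → −0.035), dose-linear relaxation
  under novobiocin anchored at Δσ = 0.00195/0.00156 for 17 µg/mL,
  clone-specific supercoiling optima linear in spacer GC, mirrored
  treated/untreated endpoint plates, dose gradients, time courses, EMSA
  titrations and Golden Gate (BsaI) oligo designs.
* **Screen statistics** — blank-corrected RFU/OD600, per-length
  summaries, weak/strong extreme groups (k = 48), TG-motif enrichment
  with Wilson CIs, per-step Welch/BH melting comparisons, the
  treated/untreated **sensitivity ratio**, removal of the
  strength bias by regressing log2 ratio on log10 strength
  (corrected ratio = 2^residual, neutral at 1), Spearman
  strength–sensitivity statistics, per-GC-bin up/down count ratios, and
  the growth-phase **timing preference** (signal at the OD600 = 0.3
  crossing over the final signal).
* **EMSA fitting** — fraction bound from band intensities and
  per-replicate nonlinear least squares of the Hill equation
  θ = Pⁿ/(K_Dⁿ + Pⁿ), with replicate-level K_D mean ± SE.
* **Native promoters** — RNA-seq-like relative expression (average gene
  ≡ 1), promoter strength as the temporal maximum, sigma70 consensus
  filtering (≤3 total mismatches) and spacer-length distributions.

See `docs/methods.md` for the model details and numerical choices.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data (seed 1 by default) and write tidy tables under `results/`:

```bash
python analysis/01_simulate_screen.py          # library + mirrored screen
python analysis/02_length_vs_strength.py       # activity vs spacer length
python analysis/03_motif_groups.py             # weak/strong 48, TG motifs, logos
python analysis/04_emsa_kd.py                  # Hill fits for the two EMSA promoters
python analysis/05_supercoiling_sensitivity.py # ratios, bias correction, GC bins
python analysis/06_timing_panel.py             # 12-clone dose gradient + timing
python analysis/07_native_promoters.py         # native-promoter expression tables
```

Representative output (seed 1):

```
highest mean activity at 17 bp; control background 29 vs weakest native length 651

extended -10 frequency: weak 0.12 vs strong 0.02; mean TG count weak 1.83 vs strong 1.02

promoter  kd_true_nM  kd_fit_nM  kd_se_nM  n_hill
  SP_w01       358.0      361.1       2.4     1.9
  SP_s01       817.0      813.7      13.1     2.0
the weak promoter binds RNAP 2.3x more tightly than the strong one

strength vs ratio Spearman: -0.713 (p=1.7e-179); after bias correction: -0.016
trend across bins: Spearman -1.00 (relaxation tolerance falls as GC rises)

timing preference vs relaxation preference: Spearman -0.82
```

Reading this: promoter activity peaks at the natural 17 bp spacing and
every length clears the random-promoter background; the weakest
optimally-spaced clones are enriched for the extended −10 TG (tight RNAP
binding acts as a brake — the weak promoter's fitted K_D of ~360 nM is
less than half the strong promoter's ~815 nM); treated/untreated ratios
correlate strongly with strength until the elongation-level bias is
regressed out, after which spacer GC content alone orders the response —
AT-rich spacers tolerate or prefer relaxation, GC-rich spacers lose
activity — and relaxation-preferring clones defer their expression past
exponential phase.

The same machinery is exposed as a CLI
(`spacerscreen simulate|features|screen|emsa-fit|expression|report`) for
running the screen statistics on real plate exports with the documented
long-format columns.

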