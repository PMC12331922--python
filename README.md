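# stagdia

A toolkit for **staggered-window data-independent acquisition (DIA)
proteomics**: design of overlapping-window and gas-phase-fractionated (GPF)
acquisition schemes, demultiplexing of staggered spectra onto half-width
precursor bins, assembly and evaluation of ion-chromatogram (spectral)
libraries — including hybrid libraries tightened with unfractionated
mixed-sample runs — and the downstream label-free quantification /
differential-expression filter cascade. A first-class synthetic-data module
generates ground-truthed peptides, DIA runs and two-group study designs so
that every stage is testable end to end without instrument data.

It is aimed at mass-spectrometry method developers and computational
proteomics researchers who want a transparent, fully seeded reference
implementation of the staggered-window / chromatogram-library workflow used
in clinical-scale muscle proteomics.

## The methods in brief

**Staggered windows.** Two interleaved banks of isolation windows of width
*w* are offset by *w*/2. For a precursor range [*m*₁, *m*₂] the scheme has
(*m*₂ − *m*₁)/(*w*/2) + 2 windows — e.g. 52 windows of 24 m/z over
400–1000 m/z, or 52 windows of 4 m/z over one 100 m/z GPF segment — and
every half-width demux bin is sampled by two windows. Window edges can be
snapped onto the peptide *forbidden zones*, the quarter-offset grid
(k + 0.25)·Δ/z with Δ = 1.00045475 (averagine mass-defect spacing).

**Demultiplexing.** Per cycle and per fragment m/z channel the solver finds
non-negative bin intensities *x* minimizing ‖A x − y‖² (A = window→bin
incidence, y = window readings linearly interpolated to the cycle reference
time), resolving each fragment onto the half-width bins.

**Libraries.** Entries carry the 3–6 most intense b/y fragments
(300–1800 m/z), iRT and protein mapping. The iRT→RT calibration is a robust
affine fit; the XIC extraction window is 2·k·(residual SD). Identification
scores are cosine(library pattern, fragment areas) × fragment co-elution,
with q-values from target-decoy competition (mass-shifted, intensity-shuffled
decoys) at a 1 % FDR default.

**Quantification.** Global MS2-level normalization; peptide quantity = mean
of the top-3 fragment areas; protein quantity = mean of the top-3 peptides;
Welch t-test on log₂ intensities with Benjamini–Hochberg correction. A
protein is significant when it is present in ≥ 50 % of samples per group,
has ≥ 2 unique peptides, q < 0.05 and |log₂FC| ≥ 0.585 (a 50 % expression
difference).

## Worked example

```python
import stagdia as sd
from stagdia.quant import normalize_ms2, rollup_top3, differential_expression

scheme = sd.build_staggered_scheme(400, 1000, 24)
plan = sd.build_gpf_plan(400, 1000, 6, 2, 4)

peptides = sd.generate_peptides(n_proteins=8, seed=23)
planted = [p for p in peptides if scheme.bin_index(p.precursor_mz) is not None][:25]
run = sd.simulate_run(planted, scheme, gradient_minutes=4.0, seed=23)
demuxed = sd.demultiplex_run(run, scheme)
lib = sd.assemble_library([run], [], planted)
idents = sd.score_and_fdr(sd.extract_xics(demuxed, lib), decoy_factor=2)

_, truth = sd.simulate_two_group_study(26, 22, frac_de=0.1, log2fc=1.0,
                                       cv_within=0.2, n_proteins=120, seed=7)
norm, _ = normalize_ms2(sd.fragment_tables(truth))
res = differential_expression(rollup_top3(norm), truth.group_labels)
```

Output of the session above:

```
52 windows, 12 m/z stagger, 50 demux bins
6 GPF segments; first covers (400.0, 502.0), 52 windows
25/25 planted precursors identified at q<=0.01; XIC window 1.13 min
12 significant proteins; 12/12 planted recovered, 0 false positives
```

Reading: the 24 m/z staggered scheme and the 6-segment GPF plan reproduce
the published cycle geometry; on a noiseless synthetic run the
simulate → demultiplex → extract → score chain recovers every planted
precursor at 1 % FDR; and at the study design of 26 vs 22 samples with 20 %
within-group CV, the filter cascade recovers all planted two-fold changes
with no false positives.

A command-line interface mirrors the library (`stagdia design-windows`,
`design-gpf`, `plan-concat`, `simulate`, `simulate-study`, `demux`,
`build-library`, `identify`, `quantify`, `detest`).

## Documentation

`docs/methods.md` describes the models, the synthetic-data generator and its
limits, numerical choices and the open design decisions.
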