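# Methods

## Scope and model overview

The package implements the computational side of a staggered-window DIA
workflow: acquisition-scheme geometry, overlap demultiplexing, ion-
chromatogram library construction and peptide-centric scoring, top-3
label-free quantification with a fixed differential-expression filter
cascade, and the comparison metrics used to evaluate competing library
strategies. Commercial components of the original workflow (database
search engines, deep-learning retention-time predictors, pathway-analysis
platforms) are out of scope; where such a component feeds the pipeline, the
synthetic-data generator supplies ground truth instead.

## Acquisition-scheme geometry

For a precursor range [m₁, m₂], window width w and stagger s = w/2, the
scheme holds n = (m₂ − m₁)/s + 2 windows with lower edges
m₁ − s + k·s (k = 0 … n−1), alternating between the offset bank (even k)
and the aligned bank (odd k). This is the unique count convention that
reproduces both published cycle sizes (52 windows for a 600 m/z range at
24 m/z width, and 52 for a 100 m/z segment at 4 m/z width). Consequences:

* the s-wide demux bins tile [m₁, m₂) gap-free and every bin is covered by
  exactly two windows, one per bank;
* exactly two windows cover a single in-range bin, and the topmost edge
  window covers none — each bank carries one edge window extending half a
  window beyond the range;
* all intervals are half-open [lower, upper), which makes bin assignment
  unambiguous.

Forbidden-zone snapping moves window edges onto the quarter-offset grid
(k + 0.25)·Δ/z, Δ = 1.00045475 (averagine spacing), z ∈ {2, 3}; the shift is
bounded by Δ/(2z) ≈ 0.25 Th at z = 2. Snapping perturbs the stored edges
only; demux-bin bookkeeping always uses the nominal geometry. Both the grid
constant and the reference charge are arguments.

Gas-phase fractionation divides the range into n segments of step
(m₂ − m₁)/n, each extended by the inter-segment overlap at the top
(e.g. six 102 m/z segments with 2 m/z overlap for 400–1000 m/z); each
segment carries its own staggered scheme built on the unique (step-wide)
span. Offline high-pH fractions are pooled round-robin (fraction i → pool
i mod p), which balances pool sizes to within one fraction and mixes early,
middle and late eluters in every pool.

## Demultiplexing

Per acquisition cycle, peaks from all MS2 scans are grouped into fragment
channels by greedy single-sweep clustering at 10 ppm (default) around an
intensity-weighted running centroid. For each channel the solver builds the
window→bin incidence system restricted to the *active component*: a bin is
an unknown only when **all** of its covering windows in the cycle read
non-zero — a zero reading in either covering window pins the bin to zero,
and a channel seen only in the outermost edge window is attributed to
precursors outside the target range and discarded. The component system is
solved with non-negative least squares (`scipy.optimize.nnls`); if a system
is underdetermined (missing scans), Tikhonov rows with a relative weight of
1e-6 of the maximum reading are appended and the affected bin spectra are
flagged. Cycles missing an entire bank are skipped with a warning.

Window readings are aligned in time before solving: each window's reading
is linearly interpolated between its scan in the current cycle and the
bracketing scan of the same window in the neighbouring cycle, evaluated at
the cycle's median retention time. For signals that vary linearly over a
cycle this interpolation is exact; the test suite verifies both that exact
case and machine-precision recovery of planted per-bin intensities when all
scans of a cycle share a timestamp.

## Synthetic data

`generate_peptides` digests random (human-residue-frequency) or user
FASTA proteins with a trypsin rule (cleavage after K/R, proline suppression
switchable, ≤ 2 missed cleavages), keeps peptides of 7–35 residues, assigns
charges from {2, 3}, and computes monoisotopic precursor and singly charged
b/y fragment m/z with pyteomics. Per peptide, relative fragment intensities
are drawn once from a symmetric Dirichlet(α = 1) — the data place no
constraint on a fragmentation model — and the 3–6 most intense fragments
inside 300–1800 m/z are retained. Peptide iRT is uniform on [0, 100];
abundances are log-normal (median 10⁶, 0.5 decades SD).

`simulate_run` places Gaussian elution peaks (default FWHM 17 s) at
affine-mapped iRT positions (iRT 0–100 → 10–90 % of the gradient; per-run
shift and per-peptide jitter optional), samples cycles of the scheme at the
default 3180 ms cycle time with an MS1 scan after every 26 MS2 scans, and
truncates peaks at 5σ. All scans of a cycle share the cycle start time by
default — the cycle is short against the peak width, and this makes the
noiseless demultiplexing closure exact; `stagger_scan_times=True` spreads
scan times across the cycle to exercise the interpolation path. The noise
model adds shot noise (variance proportional to the mean) and uniform
chemical background peaks with exponential intensities. Precursors outside
every window are excluded and counted.

`simulate_two_group_study` defaults to the 26 vs 22 sample design. Between-
sample variation is log-normal with within-group CV 0.2 (a free parameter:
the biological within-group variance of real cohorts is unknown), applied
per protein per sample and shared by all peptides of the protein; planted
DE proteins (default 10 % of proteins, matching the observed ratio of
significant to quantified proteins) are shifted multiplicatively by the
planted log₂FC in group B. Peptides falling below a low detection-floor
quantile are missing in that sample, which gives the presence filter real
work. Fragment-level tables add 5 % multiplicative measurement noise.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: isotope envelopes and charge-state interference,
correlated (structured) chromatographic drift, peak-shape asymmetry,
intensity-dependent fragmentation changes, and realistic fragment-channel
collision density. Interference between co-isolated peptides does occur in
the simulator whenever fragment channels collide within tolerance; tests of
exact recovery therefore use planted sets screened for channel uniqueness,
and noisy-data tests quantify behaviour, not exactness.

## Libraries, calibration and scoring

Library entries come from simulator ground truth restricted to peptides
observed in the source runs (an external transition-list TSV can be
imported instead). Entries duplicated across fraction runs collapse onto
one (sequence, modification, charge) key with pooled run provenance.

The iRT calibration is least-absolute-deviations (median regression) at
≥ 5 anchors and ordinary least squares below; anchor (iRT, apex RT) pairs
are taken from the mixed-sample runs when present — the hybrid-library
mechanism — and from the fraction runs otherwise. The XIC window is
2·k·(residual SD), k = 3 by default, floored at 0.5 min so that noiseless
data (zero residual) still yields a usable extraction width. Because mixed
runs are acquired under the analysis conditions while fractions may carry
per-run RT distortion, hybrid calibration residuals — and therefore XIC
windows — never exceed the fraction-only ones on equal inputs; the suite
checks this over ten seeded repetitions.

Scoring: fragment traces are extracted within the calibrated RT window at
10 ppm; a candidate's score is cosine(library relative intensities,
trapezoidal fragment areas) × mean pairwise Pearson correlation of the
fragment traces, clipped to [0, 1]. Decoys shift every fragment +10 Th and
shuffle intensities (deterministically per entry key), preserving length
and charge structure. q-values use target-decoy competition with the
reverse-cumulative-minimum convention; ties rank decoys above targets
(conservative) and break deterministically by key. The default report
threshold is q ≤ 0.01; protein-level thresholds of 0.05 (run-wise) and
0.01 (experiment-wise) are exposed as configuration.

## Quantification and differential expression

Normalization equalizes per-sample median log₂ fragment areas to the grand
median; all-missing samples are left unscaled and reported. The top-3
roll-up is exactly scale-equivariant. Differential expression uses Welch's
t-test on log₂ intensities — robust to unequal group variances at 26 vs 22
samples — with BH correction over all testable proteins, then applies the
filters in order presence (≥ 50 % of samples in *each* group) → unique
peptides (≥ 2) → q < 0.05 → |log₂FC| ≥ log₂(1.5) = 0.585. No imputation is
performed; tests use available values and proteins absent from a whole
group are excluded with a flag. A `subjects` mapping averages technical
replicates per subject before testing (off by default; samples are treated
as independent). A volcano-style annotation threshold of −log₁₀(p) > 1.13
sometimes quoted alongside q < 0.05 is treated as a plotting annotation
only; the q threshold governs.

## Evaluation metrics

Completeness is per-run |proteins| / |union| × 100; library recovery is
|identified ∩ library| / |library| × 100; explained TIC is the fraction of
total MS2 ion current within 10 ppm of any accepted identification's
fragment channels. GRAVY is the mean Kyte–Doolittle hydropathy; the
hydrophobicity index is the *sum* of per-residue coefficients, by default
the same KD scale (the index is length-sensitive where GRAVY is not) — any
published retention-coefficient table can be passed instead. Overlap
counts are exclusive Venn regions at precursor (sequence, modification,
charge), peptide (sequence, modification) or protein (accession) level.
The median XIC window is reported per precursor. Radar exports are
z-scored across methods (presentation choice).

## Problem sizes and numerical choices

The test suite and examples use deliberately small problem sizes chosen to
exercise every code path: 4-minute gradients (≈ 75 cycles at 3.18 s),
20–30 planted peptides per run, 120–150 proteins × 48 samples for the
study-level pipeline, and 20 seeded repetitions for the stochastic
guarantees (identification FDR ≤ 1.5 × nominal; DE power ≥ 80 % with
empirical FDR within Monte-Carlo error of 0.05). Divisibility of the
precursor span by the stagger is checked to 1e-6 Th; channel grouping uses
10 ppm; demultiplexing tolerances and the ridge weight are documented
above.

## Known limitations

* The demultiplexer contract (interpolating constrained least squares) is a
  documented stand-in validated only against the simulator; vendor
  demultiplexers are not specified publicly.
* Exact published window-edge tables are not reproduced — only the window
  counts and the coverage invariants (gap-free tiling, two covering windows
  per bin) are asserted.
* mzML support is read-only (pyteomics); runs serialize to an internal JSON
  format.
* MaxLFQ-style delayed normalization is intentionally not implemented; the
  top-3 roll-up is the quantification model.
* Scoring has no retention-time-difference feature and no machine-learned
  discriminant; on real data its discrimination would be weaker than the
  commercial pipelines it stands in for.
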