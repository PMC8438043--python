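# Methods

This note documents the models, defaults and numerical choices behind
`ubidia`, and what the synthetic benchmark does and does not show.

## Search space

Proteins are digested with trypsin/P semantics (cleavage C-terminal to
K or R, including before proline). A lysine carrying the K-GG remnant is
a blocked cleavage site, so digestion enumerates spans first with one
extra missed cleavage allowed, then discounts remnant-blocked sites
against the missed-cleavage budget (default 1) and never places KGG on a
span's C-terminal residue. Consequently every K-GG peptide carries at
least one missed cleavage — an invariant asserted in the tests.

Modifications: carbamidomethyl-C fixed; KGG (di-glycine remnant,
C₄H₆N₂O₂ = 114.04293 Da), Met oxidation and protein N-terminal
acetylation variable, at most two variable modifications per peptide.
N-terminal acetylation is only offered to spans starting at protein
position 1 or 2 (initiator-Met cleavage convention) and, sitting on the
alpha-amine, may coexist with a side-chain modification on residue 1.
All masses are monoisotopic and composition-derived via pyteomics; the
KGG delta is computed from its formula, never taken from a printed
constant (a widely copied value of 114.0249 Da circulating in the
literature is inconsistent with the composition of two glycyl residues
and is deliberately not used). Default peptide length bounds are 7–30
residues; precursor charges 2–3 by default (2 alone in the benchmark to
keep one precursor per peptide form).

Fragment panels are deterministic: up to 5 b- and 5 y-ions at charge 1,
indices spread evenly over 2..n−1 so the panel mixes fragments that do
and do not cover the modified lysine — the class diversity the evidence
scores need. "Other candidate site" means an unmodified, non-C-terminal
lysine (a C-terminal lysine cannot carry the remnant in this search
space).

## Synthetic DIA runs

The simulator is the package's instrument stand-in and defines the
reference study conditions:

* RT grid: 480 s gradient at 1.6 s cycle time; peak σ = 3 s (±20 %
  jitter), giving ≈ 4.4 sampling points per FWHM — the sampling regime
  of a well-configured DIA method.
* A present precursor's fragments share one Gaussian elution shape,
  scaled by per-precursor Dirichlet weights (α = 2). The weights are a
  property of the peptide (its fragmentation), drawn once per precursor
  and shared across runs — this is what makes cross-run quantification
  meaningful.
* Noise: multiplicative lognormal (CV 10 %) on peak signal plus an
  additive exponential baseline (scale 30) everywhere. Absent
  precursors and decoys receive baseline only.
* Interference: with probability 0.15 per fragment, a co-fragmenting
  interferer adds a displaced Gaussian (apex shift U(2,6)·σ, amplitude
  U(1,3)× the affected fragment). Comparable-or-larger amplitudes are
  what make co-fragmentation matter in practice; with these defaults an
  interferer displaced ≥ 4σ drives the corrupted fragment's correlation
  to its clean profile below 0.5 in expectation.
* Abundances are log-uniform over 10³–10⁵; per-run linear RT shifts
  (default run 2: +4 s, ×1.02) exercise the pass-2 calibration.
* Decoys are pseudo-reversed (C-terminal residue fixed, modifications
  following their residues); sequence collisions with any target take a
  fixed mass-shift path and are flagged. This scheme preserves tryptic
  character, length and fragment count, which keeps decoy and
  false-target score distributions exchangeable — verified empirically
  (Mann–Whitney p ≈ 0.5 between decoy and absent-target composites).

What the simulator does **not** emulate: profile-mode spectra and
centroiding, mass-calibration drift, nonlinear RT warping, isotope
envelopes, and real fragmentation intensity structure. Passing tests
therefore demonstrate the correctness and calibration of the
*computational* pipeline under its stated assumptions, not performance
on raw instrument data.

## Scoring and composite

Candidate peaks are local maxima of the summed fragment trace after a
3-point moving mean; windows extend to surrounding minima, clipped to
±8 grid points, with at least 3 points (Pearson needs 3). At most the
top 5 candidates per precursor (by apex intensity) are scored.
Correlations are computed on the candidate window only — evidence is
local to the peak. Degenerate cases are defined, not NaN: constant
traces and windows shorter than 3 points give r = 0, keeping class sums
well-defined for absent fragments. Best-fragment ties break
lexicographically on (series, index, charge) with a 1e-9 relative
tolerance so that exact ties are not resolved by floating-point jitter.

The composite is an L2-regularized logistic regression on the six score
components, trained once in Percolator style: initial ranking by the
equal-weight component sum, positives = targets at q ≤ 1 % under that
ranking (topped up to 50 if fewer), negatives = all decoys; the fitted
decision function re-scores all candidates. With fewer than 50 examples
per class, or a non-finite fit, the scorer falls back to the
equal-weight sum and says so. The reference engine's neural-network
scorer is out of scope by design; the linear discriminant is the
transparent substitute.

## FDR estimation and the two-pass workflow

q-values use the target-decoy ratio FDR(t) = π₀·d(t)/max(1,t(t)),
monotonized (running minimum from the permissive end) and clipped to
[0,1]. The `qvalues()` default is the plain estimator (π₀ = 1). Inside
the pipeline π₀ is estimated from the data: nulls among targets
distribute like decoys and true hits rarely score below the decoy
median, so twice the fraction of targets at or below the decoy median
estimates π₀ (add-one guarded, clipped to 1, plain estimator below 20
decoys). Rationale: the plain estimator is conservative by the factor
#decoys/#absent-targets; on a benchmark where half the searched
precursors are present this is a factor 2, and the π₀ correction
restores FDP ≈ q (measured calibration slope ≈ 0.95) while reducing to
the plain estimator in the usual mostly-absent regime.

Pass 1 scores every precursor in every run. The library keeps targets
with global q ≤ 1 % and run-specific q ≤ 1 % in at least one run; each
library precursor's reference RT is its apex in the best-scoring run.
Per run, a linear fit of observed apexes against reference RTs (over
confident pass-1 hits) defines the pass-2 window: ±max(3 × residual SD,
3 grid steps) around the predicted RT. Fewer than 2 calibration points
falls back to an identity map with a full-width window, flagged. Pass 2
re-scores only library precursors (decoys share their target's window,
keeping the null comparable), reusing the pass-1 discriminant; the
run-specific filter is applied at both passes. The final report filters
global q ≤ 1 % and annotates run-level q, so a precursor may be
reported in a run where only pass 2 found it (match-between-runs
semantics). Realized false-discovery proportion is validated against
ground truth at the 1 % working level on the final report; the
FDP-vs-q calibration curve is measured on pass-1 q-values, because
after library filtering pass 2 contains almost no false targets at any
threshold.

## Quantification

Precursor quantity: sum over the candidate window of the mean of the
k = 3 fragment traces most correlated with the best fragment (best
included; fewer than k uses all, flagged). This is a deliberately
simple, auditable peak-area rule. Median sample scaling equalizes
per-sample medians (over present values) at the global median of
medians. MaxLFQ builds pairwise sample log-ratios as medians of
per-precursor log-ratios over shared precursors (minimum 1 shared by
default — peptide-level groups have few precursors, unlike
protein-level conventions), solves the least-squares system per
connected component of the ratio graph, and fixes each component's free
scale so summed output equals summed input over its present samples;
disconnected samples stay missing. CVs are computed on raw (unlogged)
intensities with the n−1 denominator.

## Time-course generator and substrate calling

The planted time course follows a DUB-inhibition design: conditions
DMSO vs drug, five time points (15–360 min), 4 replicates, lognormal
noise CV 10 %, logistic intensity-dependent dropout (MNAR; location
2¹⁴, scale 1 on log₂ intensity). Among 500 ubiquitinated proteins
(1–3 K-GG peptides each), 40 are degradative — one or two sites jump
U(1.5, 2.8) log₂ at the earliest time point and relax log-normally in
time, while the protein declines sigmoidally to a floor of U(0.45,
0.72)× with onset inside the observation window — and 40 more are
non-degradative (same site behaviour, flat protein). Regulation is kept
sparse at the feature level (~10 % of peptides respond) because median
scaling — the normalization this field uses — assumes most features are
unchanged; dense planted regulation would bias every contrast, which is
a property of real experiments too, not of the normalization code.

Moderated t-tests: per time point, an unpaired two-arm contrast of log₂
intensities, features present in strictly more than 50 % of the
contrast's samples with ≥ 2 replicates per arm. The empirical-Bayes
prior (d₀, s₀²) is fitted by method-of-moments on log s² with digamma
correction and trigamma inversion (Newton); d₀ = 0 reduces exactly to
the ordinary pooled t-test, d₀ = ∞ to a z-test against s₀² — both are
asserted, and the full fit is cross-checked against the reference
empirical-Bayes implementation (limma, driven through Rscript) in the
test suite. BH correction is applied within each contrast
(per-time-point volcano convention).

Substrate calling operationalizes "down by more than 20 %" as
log₂FC < log₂(0.8) with q < 0.05 at ≥ 1 post-treatment time point
(endpoint-only available as a flag). Proteome and ubiquitinome are
matched by disaggregating protein groups into single accessions.
Proteins whose sites qualify but which were never detected in the
proteome are reported distinctly as `degradation-unknown` (rapidly
degraded proteins can fall below the detection limit). Protein
inference collapses indistinguishable proteins, then selects the
minimal explaining set — exactly for instances with ≤ 16 collapsed
groups, greedily (most unexplained peptides, ties to larger sets then
lexicographic) above that, where exhaustive search would be
exponential; subset proteins are absorbed and shared peptides assigned
to every containing group.

## Benchmark problem sizes

The identification benchmark uses 2,000 present + 2,000 absent targets
with 1:1 decoys in 2 runs (≈ 8,000 chromatogram sets per run); FDP and
calibration are averaged over 10 seeds in the test suite and 5 seeds in
`scripts/acceptance.py`. The null calibration uses 10,000 features at
n = 4 vs 4; substrate recovery uses the 500-protein time course over
5 seeds. These sizes make every stochastic claim measurable with tight
Monte-Carlo error while the whole suite stays desk-scale.

## Known limitations

* No real-data ingestion is required or tested; an mzML adapter would
  slot in at the ChromatogramSet boundary.
* Site localization between alternative lysines within one peptide form
  is not scored; each positional isomer is its own precursor.
* The linear composite is weaker than a learned spectral scorer on
  realistic interference structure; the benchmark's separability partly
  reflects the simulator's Gaussian peaks.
* π₀ estimation assumes decoy/null-target exchangeability, which the
  pseudo-reverse scheme provides here; decoy schemes that distort
  length or fragment-count distributions would need re-validation.
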