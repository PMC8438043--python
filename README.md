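# ubidia

DIA-MS ubiquitinomics in Python: peptide-centric identification of
di-glycine–remnant (K-GG) peptides from data-independent acquisition
runs, two-pass target-decoy FDR control, label-free quantification,
K-GG site mapping with parsimonious protein inference, and the
time-course integration that separates **degradative** from
**non-degradative** ubiquitination after deubiquitinase (DUB)
inhibition.

The package is aimed at computational proteomics researchers who want a
transparent, fully testable implementation of this analysis stack. It
ships a seeded synthetic DIA simulator with known ground truth, so every
stage — scoring, FDR, quantification, statistics, substrate calling —
can be validated end to end without instrument data.

## The method

**Scoring.** In DIA, each fragment ion of a peptide traces an elution
profile across consecutive cycles; fragments of a truly present peptide
co-elute and therefore correlate. For every candidate elution peak of a
precursor, the scorer designates the *best fragment* — the one whose
profile maximizes the summed Pearson correlation to all other
fragments — and summarizes evidence as correlation sums partitioned by
site content: fragments whose sequence span covers the K-GG–modified
lysine and no other candidate lysine (*site-determining*), both, the
other lysine only, or neither, plus the MS1–best-fragment correlation
and a count of well-correlating fragments. A logistic discriminant
trained targets-vs-decoys (one Percolator-style iteration) combines the
components into a composite score.

**FDR.** Pseudo-reversed decoys (sequence reversed, C-terminal residue
fixed, modifications following their residues) are searched 1:1 with
targets. For a score threshold *t*,

    FDR(t) = π₀ · #decoys ≥ t / max(1, #targets ≥ t),

monotonized into q-values; π₀ is the estimated null fraction of the
target list (decoy-anchored, so the estimator stays calibrated even when
many searched precursors are truly present). The search is two-pass: an
internal library is built from precursors passing experiment-wide
**and** run-specific 1 % FDR, then re-scored inside per-run linearly
calibrated retention-time windows (match-between-runs semantics).

**Quantification.** Precursor quantity is the candidate-window area of
the mean of the k = 3 fragment traces best correlated with the best
fragment. Precursors aggregate to peptides either by averaging
median-scaled intensities or by MaxLFQ (median pairwise log-ratios
solved in least squares; the free scale fixed so summed output equals
summed input).

**Differential statistics and substrate calling.** Drug-vs-control
contrasts at each time point use a moderated t-test: residual variances
are shrunk toward an empirical-Bayes prior (d₀, s₀²) fitted by
method-of-moments on log s² (trigamma inversion), with BH q-values per
contrast. A protein group is called a **degradative** substrate when
some K-GG peptide is significantly up more than twofold (q < 0.05,
log₂FC > 1) at the earliest time point *and* the protein is
significantly down by more than 20 % (q < 0.05, level < 0.8×) at some
later time; **non-degradative** when only the site condition holds;
**unregulated** otherwise.

## Worked example

Simulate two DIA runs with shared ground truth (40 present + 40 absent
K-GG precursors plus 1:1 decoys), search them, and quantify:

```sh
ubidia --seed 7 simulate --out sim --n-proteins 30 \
       --n-present 40 --n-absent 40 --n-runs 2
ubidia --seed 7 search --runs sim/run1.tsv --runs sim/run2.tsv \
       --report report.tsv --quant quant.tsv
```

`report.tsv` contains one row per (run, precursor) passing the global
1 % FDR filter, with score components, q-values and apex RT:

```
# ubidia_version=0.1.0
# config_hash=da9d20f315d2
# seed=7
run  precursor_id  decoy  composite  q_global  q_run  apex_rt  ...
```

The same pipeline as a library call, in the noise-free limit where every
planted quantity must be recovered exactly:

```python
>>> from ubidia import run_benchmark
>>> run_benchmark(seed=1, scale="micro")
{'config_hash': 'e5dfc8c43712', 'seed': 1, 'scale': 'micro',
 'fdp': 0.0, 'ratio_recovery_max_abs_err': 0.0, 'n_reported': 50}
```

`fdp` is the realized false-discovery proportion of the report against
the simulator's ground truth (0: no absent precursor was reported);
`ratio_recovery_max_abs_err` is the largest deviation of the measured
run2/run1 log₂ intensity ratio from the planted twofold difference
(0: quantification is exact without noise); all 50 planted precursors
were identified.

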