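# Methods

## Variant-peptide generative model

A SAAV is a protein-level substitution: `ref → alt` at a 1-based residue
position. The database is built by applying the substitution to the parent
sequence and re-digesting the *mutated* protein, not by editing the
wild-type peptide string. The distinction matters exactly when the
substitution creates or destroys a K/R cleavage site: the mutant peptide
spans then differ from the wild digest. Such peptides are retained and
flagged `span_changed`, with the shortest covering wild-type peptide
attached for reference; dropping them would silently lose a class of
detectable variants.

Digestion follows the classic trypsin rule — cleavage C-terminal of K/R,
suppressed when the next residue is proline — with protein termini always
counting as boundaries. The proline suppression is a flag (default on)
because search-engine dialects differ ("Trypsin" vs "Trypsin/P") and the
choice is rarely recorded; both dialects are reproducible here. N-terminal
methionine is not auto-clipped. Defaults of ≤2 missed cleavages and a
7-residue minimum length mirror common identification settings. One event
per variant peptide record: co-occurring nearby substitutions are not
combined, matching how SAAV tables are reported.

A candidate whose mutant sequence occurs verbatim among the wild-type
peptides of the whole proteome cannot evidence a variant and is removed.
I/L folding (mapping I to L on both sides before comparison, because the
two residues are isobaric and indistinguishable in spectra) is available
but off by default; an I↔L substitution is sequence-ambiguous under
folding and survives only with folding disabled, so the flag is reported
with every database build.

## Cohort specificity and counting semantics

An observed event is specific to cohort C when seen in ≥1 sample of C and
0 samples of the contrast cohort, shared when seen in both. Observations
from cohorts outside the contrast (adjacent-normal PN, liver-metastasis
focus LM) are tracked but excluded from the NM/MT contrast by default.
"Number of SAAVs" per protein counts *occurrences* — each (sample, event)
observation once — not distinct sites: one site carried by eight patients
contributes eight. The packaged fixture tables encode this convention, and
the three classes partition the observed events, so class totals sum to
the number of observed (sample-deduplicated) occurrences.

Two of the transcribed fixture rows print a site whose alternate letter
disagrees with the wild/mutant peptide pair alongside it; the recomputed
*position* always agrees, so the consistency check validates position and
reference letter, and the two letter mismatches are annotated in the
fixtures' `note` column rather than silently corrected. The MT-specific
table prints 7 protein rows while the accompanying text counts 5 proteins;
the fixture reproduces the rows (their occurrence total, 11, is
consistent).

## Quantification and differential expression

Raw label-free intensities are log2-transformed after converting zeros to
missing (log of zero is undefined and a zero LFQ intensity means
non-detection, not abundance), then each sample is centred on its median
over observed entries — making normalization idempotent with the medians
exactly 0. Complete-case filtering precedes testing.

The per-feature test is Welch's unequal-variance t-test by default
(configurable to Student's); log2 fold change is mean(B) − mean(A). A
feature is called differential only when three gates hold together:
|log2FC| ≥ log2(2), raw p < 0.05, and BH q ≤ 0.05. Published pipelines are
ambiguous about whether the raw-p or FDR gate (or both) applies, so the
conjunction is enforced with each threshold independently configurable and
logged. Zero-variance features with equal group means get p = 1 under a
warning instead of NaN. Summary percentages are computed against the
significant-feature total and rounded half-away-from-zero at the printed
precision (two decimals by default), since reported tables round
inconsistently at the last digit.

BH adjustment is the standard step-up (via statsmodels), verified in the
suite against the hand-applied definition.

## Multi-omics integration

Segments are summarized per gene by the length-weighted mean of
overlapping segment values (a `max_overlap` alternative takes the single
largest-overlap segment). Discrete GISTIC-style calls are out of scope
since segmentation itself is not re-implemented. Genes with no overlapping
segment are flagged absent (NaN), never imputed.

Per-gene Spearman ρ (mid-ranks for ties, pairwise-complete samples) is
computed for each layer pair across shared samples; a gene enters the
layer mean when it has at least `min_samples` (default 5) complete pairs.
Per-gene p-values are BH-adjusted. Concordant sets require
direction-consistent differential calls at mRNA and protein level
(configurable off), intersected with the copy-number-changed gene set;
chromosome tallies rank descending with ties broken by chromosome label
order 1..22, X, Y — the tally takes no stance on which hotspots are
"strongest" beyond the count ordering.

## Survival

Kaplan–Meier estimation and the Mantel–Haenszel log-rank test are
delegated to lifelines behind the module surface; the test suite checks
both against direct-formula oracles. Median dichotomization: high =
strictly above the median of usable samples; ties at the median go to the
low group (deterministic, recorded on the result object). The cutpoint
choice (median vs tertile vs optimal) is genuinely open in most published
univariate analyses; median is the default here and the only policy
implemented. Cox modelling is out of scope.

## Synthetic data: what it emulates and what it does not

The generators reproduce the *structure* of a paired tumour-cohort study:
21 NM + 23 MT samples (44 paired PN), planted substitutions in the three
cohort classes (12 NM-only, 11 MT-only, 26 shared — the scale of the
fixture tables), peptide detection as independent Bernoulli dropout at
rate 0.8 with log-normal intensities, and exponential survival with a
group hazard ratio of 3 at a baseline hazard of 0.02/month with 30%
censoring. Proteins are i.i.d. letters with K/R frequency 1/14 so the mean
tryptic fragment length lands near 14 residues.

The CNV→mRNA→protein cascade draws a latent per-gene copy-number
log-ratio, adds Gaussian noise to produce mRNA, and again for protein. The
two noise scales are set by nested bisection against the realized data:
the inner search calibrates protein noise until the mean per-gene Spearman
mRNA–protein correlation hits its target (default 0.53), the outer search
calibrates mRNA noise for the CNV–protein target (default 0.41). Bisection
on the achieved statistic was chosen over a closed form because it is
robust to any monotone link and to the finite-sample rank statistics
actually used; targets above 0.99 are rejected as unreachable. Default
problem size is 150 genes × 30 samples, chosen so the calibration and its
verification run in seconds while per-gene rank correlations at n = 30 are
still meaningful. A `de_fraction` (default 0.1) of genes receives a ±1.5
log2 shift in group-B samples at the latent copy-number layer, which
propagates down the cascade and defines the planted triple-concordant
truth.

What the generators deliberately do not model: peptide-level biases
(length/hydrophobicity-dependent detectability, shared peptides between
homologous proteins), intensity-dependent missingness, correlated genes or
chromosomal segment structure beyond one segment per gene, clonal
heterogeneity, and non-proportional hazards. Passing the recovery tests
therefore shows the pipeline's logic is correct under the stated design,
not that it is robust to these real-data complications.

## Numerical choices and degenerate inputs

- Coordinates are 1-based inclusive everywhere (`ACC_start_end` span
  notation end-to-end; no conversions).
- Writers never reorder rows and use pandas' round-tripping float
  formatting, so write→read→write is byte-stable.
- Missing values serialize as empty strings; `NA`/`NaN` accepted on read
  under a lenient flag (quantification exports vary).
- Constant vectors and <3 complete pairs make Spearman undefined: NaN with
  a warning, excluded from layer means.
- All-identical groups in rank tests: statistic 0, p = 1, warning.
- Zero events in both survival groups: log-rank returns (0, 1) with a
  warning.
- Rank-sum comparisons use the exact distribution for small tie-free
  samples and the tie-corrected normal approximation otherwise (scipy's
  policy); three or more groups switch to Kruskal–Wallis.

## Known limitations

- Exact string matching only between observed peptides and the database;
  no spectrum-level scoring, FDR re-estimation, or intensity-based variant
  quantification.
- SAAV means substitution: stop-gains, indels and splice isoforms are out
  of scope.
- Gene-level CNV assumes shared chromosome naming (labels 1..22, X, Y) and
  validates it rather than harmonizing dialects like `chr7`.
- The CLI's `run-all` is a demonstration pipeline over the synthetic
  generator; real studies would drive the library functions directly with
  their own inputs.
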