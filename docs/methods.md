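# Methods

## The analysis

The package implements the downstream inference for unamended dark
incubations of coastal seawater in which heterotrophic flagellates (HF)
bloom on bacteria. Microscopy gives cell-count curves for bacteria, HF,
phototrophic flagellates (PF) and *Synechococcus*; metatranscriptomes taken
roughly daily give (i) a community transcript x sample TPM table with
KEGG-ortholog (KO) and taxon annotations, (ii) protein- and
nucleotide-level alignment tables of transcripts against reference
proteomes/CDS, and (iii) per-species CDS read counts with effective
lengths. From these the pipeline derives growth-state labels, highly
expressed genes, fold-change flags against a housekeeping baseline, a
verified list of reference species present, normalized per-species
expression, and finally bacterivory marker genes supported both by
community fold change and by a heterotroph-vs-phototroph randomization
test.

## Growth states

Samples are labeled lag / growth / decline from the HF curve. Growth
begins at the first counted time point whose HF count reaches
`onset_ratio` (default 2) times the baseline of all preceding counts and
never falls back below its own level before the peak. The baseline is the
geometric mean of the preceding counts: on a clean flat lag this equals
their minimum, but under multiplicative counting noise a running minimum
drifts low and triggers growth too early, while the geometric mean is
unbiased in log space. Decline begins strictly after the peak; the peak
point itself belongs to growth and ties resolve to the later point.

The peak is located by a changepoint fit rather than the raw argmax: the
curve is modeled as a monotone (isotonic) rise followed by a log-linear
exponential decline, and the boundary index minimizing total squared error
in log space wins. Near the peak the curve is almost flat, so the raw
argmax flips between plateau points under even mild counting noise; the
changepoint uses the steep decline flank as leverage. On clean curves it
reduces to the counted maximum.

Samples between counted time points inherit the state of the nearest
count (ties to the earlier point). Classification is invariant to uniform
count rescaling (cells/mL vs cells/L).

Measured recovery of planted labels (default study conditions, 15 seeds):
100% with noiseless counts, 95.5% at the default 10% counting error, and
91.6% if the counting error is pushed to 20% — residual errors are samples
falling within half a count interval of a phase boundary, which are
intrinsically ambiguous at that noise level.

A validation-only PCA ordination is computed on
`log2(count / library size x 1e6 + 1)`-transformed counts (any monotone
variance-stabilizing transform serves here; this one is dependency-free
and configurable) with the mean silhouette of the state grouping reported.
It never modifies labels.

## Community expression

- *Expressed* transcripts have >= 2 TPM in at least one sample (inclusive).
  Filtered tables are **not** renormalized: re-quantification is outside
  this package's scope, so retained TPM keeps its original scale and an
  explicit `renormalize_tpm` rescale is provided instead.
- KO tables pool the full TPM of every transcript into each KO it is
  annotated with; a transcript with two KOs therefore counts twice until
  grouping. Annotation-overlap is quantified as
  `overlap(A,B) = 100 * |shared transcripts| / |transcripts of A|`
  (asymmetric), and KOs are merged by single-linkage components of the
  graph with an edge when either direction reaches 50% (configurable).
  Group TPM pools the union of member transcripts, counting each once.
  When two KOs share transcripts but neither direction reaches the
  threshold, the duplication persists by design — the grouped table is a
  deduplication of *strong* overlaps, not a partition.
- Highly expressed genes have mean TPM strictly above 500 over the
  growth-state samples of at least one incubation. Whether the mean should
  run over all samples or growth samples only is ambiguous in the source
  material; growth-only is the default (`growth_only=False` switches),
  since the list is framed as growth-state genes.
- Housekeeping genes are an input list (one KO per line), not an
  inference; missing ids warn, an empty intersection is an error because
  the fold-change baseline would be undefined.

## Fold change

Per incubation, `fc = (mean growth TPM + eps) / (mean lag TPM + eps)` with
`eps = 0.01` TPM so genes silent in lag stay finite. The baseline is the
arithmetic mean of the housekeeping genes' fold changes (geometric
available behind a flag, since fold-change distributions are naturally
log-scaled). A gene is flagged when its fold change exceeds the baseline
in at least 3 of 4 incubations; genes absent from an incubation count as
not exceeding (conservative). Fold changes are computed on state means,
not matched sample pairs — pairing is impossible with unequal sample
counts per state.

## Species detection

Protein hits are filtered first — identity strictly above 90%, alignment
length at least 50 residues — and only then is the top hit taken; the
order matters and is pinned by a test. "Top" means highest bitscore; a
transcript whose top score (bitscore equal after rounding to 2 decimals,
or equal e-value with bitscores within rounding) is shared by two or more
species is discarded as ambiguous. Species reaching 100 assigned
transcripts (inclusive) in some incubation become candidates. Each
candidate is verified at the nucleotide level: per transcript only the
best hit against the species' own CDS votes, and the species is accepted
iff the median identity is strictly above 99%; otherwise the signal is
attributed to a close relative (the empirically observed 90-95% identity
band). Candidate nomination counts transcripts after tie removal,
matching the stated processing order.

## Per-species normalization

Counts are divided by effective length, rescaled per sample to sum 10^6,
incremented by a pseudocount of 1 per CDS, rounded half away from zero
and capped at 10^6 (pseudocount and rounding configurable — the exact
historical recipe is not fully specified, so this is documented as the
package's own convention). TMM factors follow the canonical edgeR
algorithm: reference = sample whose 75th percentile of library-scaled
counts is closest to the mean; genes zero in either sample dropped;
M-values doubly trimmed (30% per tail on M, 5% per tail on A);
inverse-asymptotic-variance weighted mean; factors rescaled to geometric
mean 1. The implementation was cross-checked against edgeR's
`calcNormFactors` during development and ships with an independent
explicit-loop oracle in the test suite (agreement to 1e-10). Note that
proportional columns yield factors of 1 — the library-size difference is
carried by the library size, not the factor — and that exact
scale-invariance holds for the unweighted trimmed mean only, because the
precision weights depend on library size. CPM is
`(count + prior) / (library x factor) x 1e6` with prior 0.5 (0 gives
exact per-million columns). TMM runs per species by default (each
species' profile is self-contained); a pooled mode exists behind a flag.

## Trophic comparison and markers

Relative expression is a gene's share of its species' total CPM in one
sample. Genes absent from a species' annotation yield *no* observation
rather than a zero (a flag allows zero-imputation for sensitivity
checks). Mixotrophs are carried through descriptively but excluded from
the two-group test. For genes with at least 15 observations (inclusive)
in both heterotrophs and phototrophs, a one-sided randomization test runs:
statistic = difference of group means (medians optional), null built by
shuffling trophic labels over the pooled observations, 10,000 permutations
by default, and `p = (1 + #{perm >= obs}) / (n_perm + 1)` — the add-one
estimator never returns zero. Permutations compare with a 1e-12-scaled
tolerance so label shuffles that merely reorder a floating-point sum still
count as ties. Genes untestable for lack of phototroph observations
qualify instead through an imbalance rule: at least 15 heterotroph
observations and at least 5x (configurable; the underlying cutoff is
qualitative) as many as phototroph ones. No multiple-testing correction
is applied; results are reported gene by gene at the nominal alpha = 0.05.
Observation-level shuffling treats observations as exchangeable even
though observations within a species are correlated; a species-level
block-permutation mode is provided as the conservative alternative.
Final markers are genes that pass the trophic test (or imbalance rule)
AND carry the fold-change flag.

## Synthetic data

The generator's defaults are the study conditions: 4 incubations sampled
4-6 times over 8 days, bacteria from ~8x10^5 to ~2x10^6 cells/mL peaking
around day 4, HF from 5-10x10^2 to 7-13x10^3 cells/mL peaking around day
5-6 (a lagged logistic reaching the peak, then exponential decline; PF and
*Synechococcus* decay exponentially in the dark), 20,000 transcripts of
which 30% carry a KO (800 KOs), 50 planted marker KOs at 4x growth/lag
fold change, 104 housekeeping KOs at 1x, 25 photosynthesis KOs decaying to
near zero by decline, 8% of annotated transcripts with two KOs, 20
reference species (50% present at ~0.4% nucleotide divergence, 30%
relatives at ~7.5%, the rest absent), trophic modes at 48/32/20%
heterotroph/mixotroph/phototroph, a 4x heterotroph/phototroph
relative-expression effect, and lognormal expression noise with CV 0.3.

Choices worth stating:

- **Noise model.** Mean-preserving multiplicative lognormal noise —
  standard for TPM-scale dispersion. Microscopy counts carry their own,
  smaller error (`count_noise_cv`, default 0.1): counting a few hundred
  cells under epifluorescence is a different error process from RNA-seq
  dispersion.
- **Markers are highly expressed.** Marker KOs get a 5x baseline
  expression boost, since the bacterivory candidates this pipeline looks
  for are by construction among the most expressed growth-state genes.
  With markers prominent, TPM closure (columns sum to 10^6) visibly
  depresses the background during growth, as it does in real
  compositional data.
- **Closure balancing.** Background transcripts are rescaled per state so
  the expected raw column total is state-independent; the planted marker
  fold change and the housekeeping ratio of 1 then survive TPM
  normalization *in expectation*, which is what the recovery tests
  measure.
- **Alignment tables are generated directly** (no sequences, reads or
  assembly). Present species emit nucleotide identities centered ~99.6%,
  relatives 90-95%; a configurable fraction of transcripts receives an
  equal-score second top hit to another species (the tie fixture), and
  sub-threshold decoys (short or <90% identity) exercise the filters.
  Synthetic e-values are a monotone map of bitscore without saturation,
  so distinct scores never collide.
- **Species counts.** Per-species gene shares sum to one, with marker
  shares scaled by the trophic-mode effect (sqrt of the effect for
  mixotrophs), so the expected heterotroph/phototroph ratio equals the
  configured effect exactly. Heterotroph depth rises from lag to decline,
  phototroph depth falls. A couple of marker genes are absent from all
  phototroph annotations to exercise the imbalance rule.
- **Determinism.** One integer seed feeds independent sub-streams per
  generator; identical (config, seed) reproduce every table byte for
  byte.

What the generator does **not** emulate: sequence-level structure,
assembly artifacts, isoforms, real taxonomic composition or seasonal
succession, per-sample sequencing-depth variation (exposed as a free
parameter rather than matched to any real depth), or correlated noise
between genes. Passing tests therefore show that the inference rules
behave as specified under the assumed statistical structure, not that
they are robust to every artifact of real metatranscriptomes.

## Problem sizes and runtime choices

The test suite scales simulations down (4,000 transcripts / 400 KOs /
10 species) while keeping every structural feature, and reduces
permutations where many replicate tests are run (2,000 per gene for the
1,000-gene type-I calibration and the 500-gene power check); single-gene
analyses use the full 10,000. `scripts/acceptance.py` re-runs everything
at the default study conditions.

## Known limitations

- The fold-change stage has no dispersion model; it flags relative to the
  housekeeping distribution only, as intended.
- Fold-change exceedance on null data follows a binomial in the number of
  incubations, so the false-flag rate depends on how prominent the
  planted markers are; at the defaults it is below 1%.
- The randomization test treats observations as independent; species with
  many samples weigh more than species with few.
- Growth-state labels near phase boundaries are uncertain in proportion
  to counting noise (numbers above).
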