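# Methods

## The consensus model

pathvote implements a cross-dataset vote-counting consensus for differential
gene expression. The unit of evidence is one dataset's (LFC, corrected p)
pair for one gene; the unit of inference is the per-gene, per-cohort
consensus call. The model deliberately avoids effect-size meta-analysis
(no inverse-variance pooling, no heterogeneity statistics): heterogeneous
RNA-Seq and microarray datasets spanning species, tissues and platforms do
not share an error model, so each dataset contributes exactly one vote.

### Significance and tallying

A cell votes when its corrected p-value is strictly below alpha
(default 0.05). p-values are assumed corrected for multiple comparisons
upstream, as emitted by GEO2R/edgeR-style pipelines; pathvote performs no
further correction and treats the corrected p as opaque. A missing
(gene, dataset) cell means "no evidence" and is skipped — it is never
imputed as non-significant-with-zero-LFC. A significant cell with LFC
exactly 0 carries no direction; it is excluded from both tallies and
logged, since the criterion presumes a direction.

### The advancement criterion

A gene advances with direction *up* iff

    n_up >= 2  and  n_up >= 2 * n_down

and symmetrically for *down*. Consequences worth noting:

- a 2-vs-0 tally advances: "at least twice the minority" holds vacuously
  for a zero minority;
- ties (k vs k) never advance;
- 3-vs-2 does not advance (3 < 4);
- the two-dataset floor is applied to the winning direction alone. The
  alternative reading (floor on total significant datasets) differs from
  ours in no reachable case: any tally meeting the 2:1 ratio with a total
  of >= 2 but a winning count of < 2 would have to be 1-vs-0 or 1-vs-1,
  and neither satisfies both conditions under either reading.

The consensus mean LFC of an advanced gene averages only the significant
datasets in its winning direction — not all datasets, and not the minority
votes. Tests verify the criterion against an independent brute-force
enumeration of the rule for every tally with up to eight voting datasets,
plus sign-symmetry and monotonicity properties.

### Pathway attribution

Votes are per-gene per-cohort; a gene shared by several pathways (e.g. HK1
in glycolysis, glycogenesis and the pentose phosphate set, or SDHA in the
TCA cycle and the ETC) carries its single vote into each containing
pathway. Cohort totals therefore count gene–pathway pairs, which is why
the packaged query universe totals 242 entries over a 220-gene union.

## Gene sets

The twelve packaged pathway gene sets are ordered symbol lists with the
rate-limiting enzyme gene(s) flagged and a declared set size. Declared
sizes are authoritative for totals; two internal discrepancies in the
source lists are surfaced as validation notes rather than edited:

- glycolysis declares 27 genes but lists 26 tokens (the missing symbol is
  not stated anywhere, and we do not guess it);
- the ETC reaches its declared 69 only by listing UQCR10 twice; the
  duplicate is removed for membership logic but counted for validation.

Symbols are uppercase exact strings. No alias or ortholog mapping is
attempted — cross-species symbol resolution belongs upstream of this
pipeline. Four obvious typographical variants in the shipped summary-table
fixtures are normalized on load through an explicit mapping
(`pathvote.fixtures.SYMBOL_FIXES`): SLCIA3→SLC1A3, SLOVL6→ELOVL6,
COX411→COX4I1, SDAHF2→SDHAF2.

## Summaries and arithmetic conventions

- Pathway-level "average LFC" is a two-stage mean: per-gene consensus
  means (over significant datasets in the winning direction) averaged,
  unweighted, over the genes of each direction group. It is not pooled
  over dataset-level cells.
- Integer percentages use round-half-up, centralized in
  `integer_percent`. Published summaries of this kind are not always
  internally consistent under any single rounding rule (we observed
  printed values such as 77% for 7/9, which rounds to 78%); only
  rounding-stable cases are used as test targets, and a zero denominator
  is defined as 0 with a warning.
- Fold-change phrasing converts an LFC to 2^|LFC| rounded half-up to one
  decimal, qualified "higher"/"lower" by sign ("unchanged" at 0). The
  same caveat applies: prose fold-changes in published tables
  occasionally deviate from this arithmetic (e.g. "1.4×" for LFC 0.56,
  which is 1.47 ≈ 1.5); only consistent cases are asserted.
- Per-pathway minimum and maximum consensus LFCs are computed and carried
  on summaries even though the headline tables print only means.

## Concordance comparison

Disease-vs-ketosis comparison is pathway-scoped: the same gene is compared
within each pathway containing it, matching the per-pathway annotation of
the summary tables. Within a pathway, the four groups — concordant,
discordant, disease-only, ketosis-only — partition the union of the two
cohorts' advanced genes (property-tested on random profiles). A gene
advanced in opposite directions in two pathways of one cohort cannot occur
by construction (one vote per gene per cohort) and is rejected defensively
when profiles are assembled from external files. Medication cohorts (AP,
MS) can be compared with the same operation; the CLI marks such reports
exploratory since they sit outside the original comparison design.

## Packaged table fixtures

The package ships, as plain TSV, the per-pathway hit lists and group mean
LFCs of six published cohort analyses (SCZ, BPD, MDD, KI, AP, MS). These
restored profiles know group means but not per-gene LFCs; summaries built
from them pass the group means through unchanged. Two source
inconsistencies are flagged rather than reconciled:

- the BPD table's entries sum to 129 against a printed total of 130; the
  fixture ships the table as printed, `reproduce-tables` reports the
  computed 129 and marks the 130 claim as a known discrepancy;
- where running text and table disagree on a gene's placement (two ETC
  concordance statements, one pentose-row column ambiguity), the table is
  taken as authoritative, except for the pentose "Downregulated: G6PD,
  GSR, RPIA" row, whose column assignment is ambiguous in the layout and
  is resolved to the ketosis column by the accompanying text.

## Synthetic-data generator

The generator emulates what a lookup query returns — a gene × dataset
matrix of (LFC, corrected p) summaries — not read counts; the pipeline
never consumes counts, so a count-level simulator would add assumptions
without adding coverage. Significance is planted by construction: a
significant cell draws its corrected p uniformly from (0, alpha), a
non-significant cell from (alpha, 1). This is sufficient because the
criterion consumes only the indicator p < alpha and the LFC sign and
magnitude.

Per gene and dataset, for a perturbed gene with signed effect ±effect_mu:
with probability `replication_prob` the cell is significant, its LFC drawn
Normal(signed effect, effect_sigma) with the sign flipped with probability
1 − `sign_fidelity`; otherwise the cell is non-significant with LFC
Normal(0, null_lfc_sigma). A null gene is significant with probability
`false_pos_rate`, its LFC drawn from the symmetric null distribution (so a
false positive's sign is random). All draws come from one seeded
`numpy.random.default_rng` stream; identical seeds reproduce matrices
bit-for-bit.

Parameter defaults and rationale:

| parameter | default | why |
| --- | --- | --- |
| n_genes | 242 | size of the packaged query universe |
| n_datasets | 8 | the ketogenic-intervention module size; tissue split 5 brain / 3 liver mirrors its composition |
| frac_perturbed | 0.16 | ≈ 38/242, the observed ketosis hit fraction |
| effect_mu | 0.6 | consensus LFC magnitudes cluster around 0.2–1.6; 0.6 is central |
| effect_sigma | 0.2 | moderate between-dataset spread; keeps sign errors from noise rare but possible |
| replication_prob | 0.8 | strong but imperfect replication |
| sign_fidelity | 0.95 | occasional discordant significant calls |
| false_pos_rate | 0.02 | sub-alpha residual false-positive rate after correction |
| null_lfc_sigma | 0.2 | null LFC noise on the scale of small real effects |
| alpha | 0.05 | the significance level of the criterion |

Every true effect has magnitude exactly `effect_mu` (per-gene effect-size
dispersion is not modeled; `effect_sigma` is per-dataset spread around the
effect). The generator also does not model inter-dataset batch effects,
platform biases, tissue-specific effect heterogeneity, or gene–gene
correlation, and plants no missing cells. Passing recovery tests therefore
demonstrates that the criterion's bookkeeping and operating
characteristics are correct under independent, homogeneous evidence — not
that real cross-study heterogeneity is harmless.

### Operating characteristics

Recovery metrics score advancement calls against the planted truth:
sensitivity (true perturbed genes advanced with the correct direction),
specificity (true null genes not advanced) and direction accuracy (among
advanced true-perturbed genes). The false-advancement probability of a
null gene has a closed form — sum over s ~ Binomial(K, f) significant
cells and u ~ Binomial(s, ½) upvotes of the outcomes satisfying the
criterion — implemented in `null_advancement_probability` and verified in
tests against an independent exhaustive enumeration of all 3^K per-dataset
outcome sequences, and against simulation within three Monte-Carlo
standard errors.

## Problem sizes

Test and acceptance runs use cohorts of 100–20,000 genes and 2–8 datasets:
large enough that Monte-Carlo checks resolve the quantities being tested
(20,000 null genes give a standard error of ~0.0035 on an advancement rate
near 0.5), small enough that the whole suite completes in seconds. The
fixture-derived quantities involve no randomness at any size.

## Numerical and degenerate-input choices

- Strict p < alpha everywhere; alpha outside (0, 1) is rejected.
- Empty matrices yield empty vote lists; empty advanced lists yield
  zero-hit summaries with undefined (None) means; empty denominators in
  recovery metrics yield NaN.
- Matrix TSV round-trips preserve missing cells exactly (empty fields) and
  carry dataset metadata in `#` header lines; floats are written with
  `repr` so read(write(m)) == m bit-for-bit.
- Gene order within pathways follows the curated lists; vote lists are
  sorted by gene symbol for determinism.

## Known limitations

- Vote counting discards effect-size precision and dataset size; a large
  well-powered study counts the same as a small one. This is intentional
  (transparency over efficiency) but means the criterion is conservative.
- The restored table fixtures cannot recover per-gene LFCs, only group
  means, so comparisons built on them report group means in the per-gene
  LFC columns.
- Symbol normalization covers only the four documented typographical
  variants; genuinely ambiguous symbols (e.g. the legacy acyl-CoA
  dehydrogenase names VLCAD/SCAD/MCAD/LCAD in the fatty-acid-oxidation
  set) are kept as listed and will simply never match a modern dataset's
  symbols unless harmonized upstream.
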