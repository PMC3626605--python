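# Methods

## Model

### Gamete formation

A parent genotype is a ploidy (2 or 4) plus an ordered list of
S-haplotypes, each a `(species, label)` pair with two functionality
flags: `style_active` (S-RNase) and `pollen_active` (SFB). Diploids
produce the two monoploid gametes at 1/2 each. Tetraploids produce
diploid gametes; under **tetrasomic** segregation every unordered pair
of the four homologues is equally likely, so a fully heterozygous
genotype {a,b,c,d} yields the six hetero-diploid classes at (1−α)/6
each, where α is the **double-reduction rate**: the probability that a
gamete carries two copies of the same parental chromosome, spread
uniformly over the four homozygous doubletons (α/4 each). α defaults to
0; the observed absence of single-, three- and four-allele gamete-side
contributions in the study progenies is the α = 0 prediction, and the
test suite contains a recovery experiment showing that α = 0.15 data at
n = 2000 are reliably distinguished from α = 0. The alternative
**disomic_fixed** mode (two fixed subgenome pairs, as in allotetraploid
sour cherry) yields only the four inter-pair gametes at 1/4 each; α
does not apply there.

Genotypes with duplicated haplotype labels are rejected rather than
modeled: the study cultivars are fully heterozygous, and duplication
would complicate class identity for no supported use case.

All gamete and class probabilities are exact `fractions.Fraction`
values. This is what lets the expected progeny distribution be emitted
as an exact integer ratio vector (1:1:1:1:1:1:6:6:6:6:6 over 36) rather
than floats that merely round to it. Floats enter only at the
simulation and χ² boundary.

### Compatibility

The *effective specificities* of a pollen grain are the distinct
`(species, label)` keys of its pollen-active haplotypes. Acceptance on
a style (the set of style-active keys of the seed parent):

1. SI disabled → accepted (null model for expected-ratio derivation).
2. ≥ 2 effective specificities and competitive interaction on →
   accepted.
3. Exactly 1 → accepted iff that key is not in the style set.
4. 0 (fully pollen-dead grain) → accepted by default
   (`accept_pollenless=True`); the opposite setting models a lethal
   pollen-part mutant that aborts the grain. Both hypotheses appear in
   the polyploid-cherry literature; the default is the one that makes
   no grain silently disappear, and the flag makes the alternative a
   one-line change.

Matching is species-scoped, so an interspecific style (e.g. *P. avium*
"Summit") never rejects *P. pseudocerasus* pollen on a shared label
like "S1": the labels denote different specificities in different
species. Eggs are never filtered — GSI acts on pollen tubes only.

`competitive_interaction=False` (every specificity independently
lethal) is provided deliberately: on a self pollination with one
pollen-dead haplotype it rejects *all* pollen, which is how the
model-ranking test shows this hypothesis cannot account for any
observed self progeny.

### Progeny phenotype classes

The genotyping assay is presence/absence PCR, hence dosage-blind: a
progeny individual is characterized by the *set* of distinct S-alleles
detected. The zygote class is therefore the union of the egg's and the
accepted pollen gamete's allele sets; progeny ploidy is not modeled.
Pollen classes may carry non-negative **transmission weights**
(relative pollen-tube performance), applied after stylar filtering and
renormalized; weights attach to pollen gamete classes, not zygotes,
and a uniform weight vector leaves the distribution invariant. The
observed zero classes beyond the S₂ rule's predictions (e.g. S₂S₅S₈ in
the "Dabai" self progeny) are *not* hard-coded anywhere; they are
representable only through weights, which keeps the mechanism question
(selection vs sampling) out of the model core.

Report ordering is two-allele classes first (natural allele order:
S2 < S13), then three-, then four-allele classes, matching the layout
of published segregation tables.

### Goodness-of-fit

Pearson χ² with expected counts proportional to the ratio vector, no
continuity correction, df = k − 1 counting all cells including
zero-ratio ones. Zero-ratio convention: expected 0 ∧ observed 0
contributes 0; expected 0 ∧ observed > 0 flags the model impossible
(χ² = +∞). This is the convention under which published fitted-ratio
statistics such as 0.357 for (6,13,15,15,0,0) vs 1:2:2:2:0:0 are
reproduced. Critical values are always recomputed from
`scipy.stats.chi2.ppf(1−α, df)` — published tables of critical-value
labels are not always internally consistent (the data source here
labels the df = 10 quantile 18.31 as df = 11 in one table and pairs a
df = 5 comparison with the df = 3 quantile once in the text), so
labels are never trusted over df. One published statistic could not be
verified by recomputation from its own printed counts
((447,267,428,285) vs 1:1:1:1) and is deliberately not asserted.

The statistic is reported at full precision and display-rounded to 3
decimals. An exact multinomial p-value (enumeration over compositions,
capped) is available for small tables; it is an optional extra, not
the default, because the published analysis is the plain Pearson test.

`find_candidate_ratios` formalizes the field habit of quoting an
"approximate ratio": it exhaustively scores every integer ratio vector
with terms in 0..max_term (deduplicated up to scaling, capped at
2×10⁶ vectors, ≤ 8 classes), ranked by χ² with lexical tie-break. It
is a descriptive device, not an inference procedure — no multiplicity
correction is applied or implied.

## Synthetic data

The generator draws progeny class counts as one multinomial sample per
replicate from the closed-form expected distribution — this *is* the
sampling model the χ² analysis assumes (independent seedlings,
fixed class probabilities). Reproducibility: a
`numpy.random.SeedSequence(seed)` is spawned once per replicate, so
replicate r is independent and individually reproducible. An
event-level mode draws each pollination (egg draw; pollen rejection
sampling with stylar acceptance and weight thinning) and is used to
cross-validate the closed form.

What the generator does **not** emulate: overdispersion between
mother-tree harvests, genotyping failure/dropout, embryo abortion,
fruit-set variation, or linkage to anything outside the S-locus.
Passing simulation tests therefore show internal consistency of model,
sampler and test — they do not show that real progenies are
multinomial.

Problem sizes used in the standard test run: type-I calibration with
2000 replicates at n = 438 (df = 10), matching the real self-progeny
size; model recovery with 500 replicates at n = 438; distortion power
with 200 replicates at n = 1200; law-of-large-numbers check at
n = 10⁵. These sizes make the suite complete in a few seconds while
keeping Monte-Carlo standard errors well inside the asserted bands.

## Packaged study data

`tetragsi.datasets` embeds the published class-count tables of the
four progenies (two self, two interspecific; 961 seedlings total) and
the published marginal rows with their fitted small-integer ratios.
Pps-S₂ is configured pollen-dead (its SFB was never detected and the
progeny data match the pollen-dead prediction exactly); Pps-S₈ is left
pollen-functional — its SFB also failed to amplify, but the plausible
cause is technical (differential amplification), and the progeny data
give no sign of a second dead haplotype. Both are plain data flags,
overridable by rebuilding the parent.

## Known limitations

- Tetraploid parents must be fully heterozygous at the S-locus.
- Mixed-ploidy gamete output (monoploid + triploid, as reported in
  grape) is out of scope; gametes are monoploid (2x parent) or diploid
  (4x parent).
- Transmission weights are inputs, not estimates: there is no ML
  fitting of weights, only the exhaustive ratio search and χ² ranking
  of fully specified candidate models.
- The χ² test is asymptotic; with expected counts ≪ 5 use the exact
  multinomial option.
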