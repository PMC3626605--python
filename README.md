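# tetragsi

Genetic analysis of S-haplotype inheritance in polyploid cherry with
gametophytic self-incompatibility (GSI).

Tetraploid Chinese cherry (*Prunus pseudocerasus*) cultivars such as
"Dabai" (S₁S₂S₅S₈) are self-compatible even though they carry functional
S-RNases. The explanation lives in their pollen: tetrasomic meiosis
produces **hetero-diploid pollen** carrying every combination of two of
the four S-haplotypes, and when both haplotypes are functional and
different, each SFB protein can detoxify the other haplotype's cognate
stylar S-RNase (**competitive interaction**), so the grain passes even a
self style. A **pollen-part-dead** haplotype (an S-haplotype whose SFB
is lost, like Pps-S₂ here) contributes no specificity: a grain carrying
it behaves like monoploid pollen of its partner haplotype and is
rejected on self styles.

`tetragsi` turns this genetics into testable arithmetic, for breeders
and geneticists working with segregation data from polyploid progenies:

- **Gamete model** — exact (rational-arithmetic) gamete class
  distributions for diploid and tetraploid parents, under tetrasomic
  segregation with an optional double-reduction rate α, or fixed
  disomic subgenome pairing (the sour-cherry mode).
- **Compatibility filter** — stylar acceptance rules with switches for
  competitive interaction, SI on/off, and pollen-part mutants.
- **Progeny model** — expected distributions over dosage-blind
  *phenotype classes* (the set of distinct S-alleles a presence/absence
  PCR assay detects in one seedling), allele marginals, pair
  co-occurrence counts, and collapsing of interspecific progeny tables
  over one parent's alleles.
- **Goodness-of-fit** — Pearson χ² against model-derived or
  user-supplied segregation ratio vectors, with the zero-ratio-cell
  convention, df = k−1, recomputed critical values, an exhaustive
  small-integer ratio search, and the ≥2 % fruit-set compatibility
  classifier.
- **Simulation** — seeded multinomial (and event-level) progeny
  generators and χ²-based candidate-model ranking.

For an n-seedling progeny scored over k classes with expected ratio
(r₁,…,r_k), the test statistic is the plain Pearson sum

    χ² = Σᵢ (Oᵢ − Eᵢ)² / Eᵢ ,   Eᵢ = n·rᵢ / Σⱼ rⱼ ,   df = k − 1,

compared with the upper 5 % χ² quantile. A cell with rᵢ = 0 and Oᵢ = 0
contributes 0; an observation in a zero-ratio cell makes the model
impossible (χ² = +∞).

The published study data — cultivars "Dabai", "Taishanganying"
(*P. pseudocerasus*, 4x) and "Summit" (*P. avium*, 2x), with the class
counts of their two self and two interspecific progenies — ship in
`tetragsi.datasets`, so the whole analysis re-runs from the library or
the CLI with no external files.

## Worked example

Expected self-progeny distribution of a fully compatible tetraploid
(all 36 gamete pairs transmitted):

```text
$ tetragsi expect --cross dabai_self --no-si --pretty
class                        probability  ratio
Pps-S1+Pps-S2                       1/36  1
Pps-S1+Pps-S5                       1/36  1
Pps-S1+Pps-S8                       1/36  1
Pps-S2+Pps-S5                       1/36  1
Pps-S2+Pps-S8                       1/36  1
Pps-S5+Pps-S8                       1/36  1
Pps-S1+Pps-S2+Pps-S5                 1/6  6
Pps-S1+Pps-S2+Pps-S8                 1/6  6
Pps-S1+Pps-S5+Pps-S8                 1/6  6
Pps-S2+Pps-S5+Pps-S8                 1/6  6
Pps-S1+Pps-S2+Pps-S5+Pps-S8          1/6  6
ratio vector: 1:1:1:1:1:1:6:6:6:6:6
```

Two-allele classes arise only when egg and pollen carry the same pair
(6 of 36 gamete pairs each collapse to their own class), three-allele
classes when they share one allele (6/36 each), and the four-allele
class from the 6 disjoint pairs — hence 1:…:1:6:…:6.

Testing the observed "Dabai" self progeny (438 seedlings) against that
model ratio:

```text
$ tetragsi gof --counts dabai_self.tsv --cross dabai_self --no-si
...
chi2	1122.315
df	10
critical	18.307
fits	false
```

The data reject the unfiltered model decisively (χ² = 1122.3 ≫ 18.3):
S₂-containing two-allele classes are missing — exactly what the
pollen-part-dead S₂ plus competitive interaction predicts — and the
surviving classes are further distorted by differential pollen-tube
performance. Searching small-integer ratios for the single-allele
marginals of the "Summit" × "Dabai" progeny (34, 6, 28, 30):

```text
$ tetragsi fit --counts singles.tsv --max-term 5 --top 5
rank	ratio	chi2
1	5:1:4:4	0.314
2	5:1:4:5	0.449
3	5:1:5:5	0.612
4	4:1:4:4	0.959
5	5:1:5:4	1.337
```

The S₂ deficit (weight ≈ 1/5 of the other alleles) is unmistakable in
every top candidate.

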