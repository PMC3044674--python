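# Methods

This note documents the models, estimators, numerical choices and known
limitations behind `islandlineages`.

## Coordinates, variants and the packaged reference

All mtDNA coordinates are 1-based inclusive on the rCRS layout
(16,569 bp).  Variants are Phylotree-style tokens: a bare position is a
transition away from the reference base, an explicit trailing base whose
purine/pyrimidine class differs from the reference is a transversion,
`d` marks a deletion, and dotted sub-positions (`310.1C`) are insertions.
Transitions print as bare positions, so `format(parse(t))` is a canonical
form and a fixpoint.

The packaged reference (`data/reference_synthetic.fa`) is a **synthetic
stand-in**: random base composition at rCRS length, with the positions
whose reference state the analyses consult pinned to their documented
values (the 303–315 poly-C tract, 16182/16183, 16189, 16360 = C so that
`16360A` is a transversion, 16519 = T).  Every analysis in the package is
relative to this packaged reference, so results are internally coherent;
they are not base-for-base comparable with analyses against the real
rCRS.  The packaged haplogroup tree
(`data/phylotree_subset_synthetic.yaml`) likewise carries the surveyed
clades with the documented B4a1a4 motif (np 4025 + 16360A) and the F1a1d
motif (16399, 11380); other branch motifs are illustrative placeholders,
deliberately not a Phylotree mirror.

Hotspot filtering defaults to: transitions at 16519, indels in the
303–315 poly-C tract, and the 16182C/16183C companion transversions.
These recur so often that haplotype comparisons conventionally exclude
them; the list is a parameter everywhere it is used.

Mutation classification translates codons under the vertebrate
mitochondrial code using the standard 13-gene protein-coding annotation
(including the light-strand ND6 and the ATP8/ATP6 and ND4L/ND4 overlaps).
A substitution in overlapping genes is synonymous only if silent in every
reading frame; indels and control-region variants are never synonymous;
sites in incomplete terminal codons fall through to `other`.

## Haplogroup assignment

A sample is assigned to the node maximising
`score = |path variants present| − |path variants absent|` over the
variants accumulated from the root, with ties broken by greater depth and
then name.  The miss penalty of 1 per absent path variant tolerates
back-mutations and partial sequencing coverage — exact-match semantics
would misclassify real partial genomes — and every miss is reported as a
potential back-mutation (`@` flags).  On homoplasy-free input the
assignment provably recovers the generating clade, which the tests check
for every packaged clade.

## Diversity and neutrality

Gene diversity is Nei's unbiased `H = n/(n−1)(1 − Σp̂²)` with the
sampling variance of Nei (1987).  Tajima's D uses the 1989 constants
(`D = (π − S/a₁)/√(e₁S + e₂S(S−1))`), is an error when `S = 0`, and
reports a significance band from the beta approximation (D rescaled to
its minimum/maximum with mean 0 and variance 1).  The implementation is
checked against an explicit re-derivation on toy alignments, against
tskit's `Tajimas_D` on coalescent samples, and against the near-zero
neutral expectation over 2,000 msprime replicates.

## AMOVA and fixation indices

One-level AMOVA decomposes squared inter-individual distances:
`SSD_total = Σ_{i<j} d²_ij / N`, `SSD_within = Σ_g Σ_{i<j∈g} d²_ij / n_g`,
with `Va = (MS_among − MS_within)/n̄`, `n̄ = (N − Σn_g²/N)/(G−1)`, and
`Fst = Va/(Va+Vw)`.  Distances are: identity (0/1) for haplogroup labels,
number of differing loci for Y-STR profiles (an Rst-like
sum-of-squared-steps mode is selectable; the source analysis does not
name its choice), and pairwise differences over HVS-1 (nps 16037–16365)
for mtDNA.  Permutation P-values shuffle group labels and use the
`(b+1)/(m+1)` estimator so finite permutation counts never produce
P = 0.  Negative variance-component estimates are reported as computed —
clipping would hide estimator behaviour the tests rely on (balanced
identical compositions sit slightly below zero).

The Monte-Carlo exact differentiation test orders 2 × K tables by their
conditional hypergeometric probability and estimates the tail by
permuting pooled individuals; on 2 × 2 tables it converges to the
two-sided Fisher exact test.

Neighbor joining follows Saitou–Nei agglomeration with the Q criterion;
ties break deterministically by label order, and the final three nodes
are resolved by the three-point formulas.  Exact recovery on additive
metrics and topological agreement with scikit-bio's implementation are
tested.

## ρ dating

`ρ` is the mean number of mutations (restricted to a calibration's region
and mutation class) separating sampled lineages from the clade founder;
`age = ρ × years-per-mutation`, rounded to the nearest year.  The
Saillard standard error is `σ² = n⁻² Σ_b ℓ_b n_b²` over lineage-tree
branches; a star genealogy collapses it to `√(total)/n`.  When the data
are known to be homoplasy-free (`assume_infinite_sites=True`) the lineage
tree is read off the haplotypes themselves: each variant marks one branch
whose sampled descendants are its carriers, giving
`σ² = n⁻² Σ_v c_v²`.  The 95% CI is `age ± 1.96 σ × rate`, floored at 0.

Calibrations are packaged constants: synonymous coding substitutions
(transitions *and* transversions) per 7,884 y (Soares) or 6,764 y
(Kivisild) over nps 590–15990, and HVS-1 transitions per 19,171 y
(Soares) or 20,180 y (Forster–Saillard) over nps 16090–16365.  One ρ
computed from synonymous mutations serves both coding calibrations.
Exact-match tests target the Kivisild and Forster–Saillard columns; the
published age table was evidently computed from unrounded ρ, so the
full-table consistency sweep allows ±1 year.

Y-STR ρ dating uses the mean single-step distance from a founder
haplotype (default: the within-haplogroup modal haplotype) with
`age = ρ/(L·μ) × 25 y` at `μ = 6.9 × 10⁻⁴` per locus per generation.  The
duplicated DYS385 locus is excluded by default — the per-locus median and
single-step distance of an unordered pair are ill-defined — and can be
included by flag (the 16-locus worked example in the tests does so).
DYS389II is stored as reported, without subtracting DYS389I.

## Median-joining networks

The ε-relaxed minimum spanning network links every haplotype pair whose
direct distance is within ε of their single-linkage merge level; at
ε = 0 (the default, matching common practice) it is exactly the union of
all minimum spanning trees.  Median insertion then repeatedly adds the
per-locus median of a connected triplet whenever it shortens the network,
to a fixpoint, and prunes medians whose removal does not lengthen it.
Edge insertion and candidate order are fixed by sorting, so the network
is invariant to input order — the published algorithm leaves these
tie-breaks open, and reproducibility requires fixing them.

## Genealogy–phylogeny concordance

The composite NRY tree grafts, under each Y-SNP haplogroup, a
deterministic-Kruskal minimum spanning subtree of the Y-STR haplotypes
rooted at the modal haplotype; each profiled man is one leaf.  The
concordance statistic is the minimum number of pairwise crossings of the
leaf-to-category link lines, where the category axis may be reordered
freely and leaves only by rotating internal nodes (links sharing a
category never cross).

One-sided crossing minimisation is NP-hard, so the optimiser alternates
two passes: each internal node's children are reordered using the exact
pairwise precedence-cost matrix (subset DP when a node has ≤ 6 children,
barycenter seeding plus insertion local search otherwise), and the
category axis is reordered the same way.  Instances whose entire rotation
space is small (≤ 720 layouts) are solved by joint exhaustive search, so
small cases return the true minimum — verified against brute-force
enumeration.  The result is never worse than the identity layout.

The permutation test shuffles the leaf-to-category assignment, re-runs
the optimiser per permutation (conservative; a flag freezes the observed
orders instead) and reports `p = (1 + #{crossings < observed})/(n+1)`.
Strictly-fewer counting mirrors the statistic's published definition; a
flag switches to ≤ counting, which is the variant used for the null
uniformity property test because the crossing count is discrete and
strict counting is anti-conservative under ties (a star tree, whose
layout always reaches zero crossings, is the extreme case).  A single
category is a degenerate design and an error.

## The synthetic island

The simulator is a discrete-generation forward Wright–Fisher model of
`n_villages` villages of constant size (half men, half women).  Each
offspring slot draws its father from the home village with probability
`1 − m_m` (else another village) and its mother's natal village is
another village with probability `m_f` — women move at marriage, men do
not, i.e. patrilocality.  Sons inherit patriline label, Y-SNP haplogroup
and Y-STR haplotype (per-copy stepwise ±1 mutations, both DYS385 copies
mutable); all children inherit the mother's mtDNA variant set with
Poisson mutation counts per lineage-generation.  Coding mutations land
only on sites that are synonymous on the packaged gene map, so the dating
filters count exactly what was simulated; positions recur within a
lineage are redrawn (infinite sites per lineage; independent recurrence
across lineages is possible but rare).

Defaults emulate the Yami survey conditions: 6 villages × 30 adults
(~180 people, 90 women; the survey sampled 79 individuals), 120
generations of 25 years
(~3,000 years, the genetically estimated settlement window), `m_f = 0.5`
(inter-village marriage common for women), `m_m = 0` (sedentary men),
2 Y and 3 mtDNA founding lineages per village, mutation rates equal to
the calibration rates (HVS-1 transitions at 25/20,180 per
lineage-generation, synonymous coding at 25/6,764, Y-STR at 6.9 × 10⁻⁴
per locus per generation), and Y-SNP founder frequencies patterned on
the Yami sample.  Ancestral families are the founding patrilines
(village + Roman numeral); extended families are the patriline branches
alive 4 generations before the present, so they nest within ancestral
families by construction, as in a patrilineal kinship survey.

What the generator emulates — and does not.  It reproduces drift, founder
effects, sex-biased migration and the resulting contrast between paternal
and maternal village structure; after 120 generations drift typically
fixes one patriline per village, matching the low paternal founder count
the real survey reports.  It does not model population growth,
selection, inter-island gene flow, genealogy transcription errors or
adoption, and its founder haplotypes are random motifs rather than real
clade motifs — so passing tests demonstrate correct estimator behaviour
under the stated demographic model, not agreement with any particular
real dataset.

## Test and acceptance problem sizes

Stochastic checks are sized to be decisive yet quick: 2,000 coalescent
replicates for the Tajima's D null mean; 200 replicates for each
uniformity KS test (α = 0.01); 100 simulation replicates each for the
CI-coverage and sex-biased-Fst properties; 999 permutations for headline
concordance runs and 199 inside the test suite.

The CI-coverage experiment uses the design the ρ estimator assumes: 20
mutually independent 120-generation lineages, realized by the simulator
as isolated single-pair villages, dated against their true founders with
the star-form σ (95/100 coverage measured).  Coverage on a *single*
island-wide founder clade at the patrilocal defaults is much worse
(~36–64% depending on pooling), because near-complete matriline
coalescence leaves effectively one lineage with a Poisson mutation count
below 1, so ρ = 0 with a degenerate CI is the modal outcome.  This is a
real property of ρ dating on drifted island isolates — small-island clade
ages date the local MRCA, not the settlement — and is the reason founder
dating of such studies leans on regionally pooled clade samples.

## Known limitations

- The reference and haplogroup motifs are synthetic stand-ins (above);
  analyses are internally consistent but not comparable site-by-site with
  rCRS-based publications.
- The crossing optimiser is a documented approximation on large
  instances; only small-instance results are certified minimal.
- The MJ implementation adds one median per round (deterministic) and is
  intended for the small within-haplogroup networks of this problem
  domain, not thousand-haplotype datasets.
- Permutation and Monte-Carlo P-values are estimates with resolution
  `1/(n_perm + 1)`.
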