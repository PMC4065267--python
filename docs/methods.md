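# Methods

## Model and scope

The package models a sporophytic self-incompatibility (SSI) system of the
Brassicaceae type. The S-locus is a single Mendelian locus; an S-haplotype
comprises one or two tightly linked SRK-like sequence labels (local
duplication within the locus makes two-label haplotypes the common case,
and one label may be shared between two haplotypes that nevertheless confer
distinct incompatibility specificities). Individuals are diploid; pollen
phenotype is determined by the diploid genotype of the pollen donor, so
dominance/recessivity between the two haplotypes of a heterozygote is
possible and is modelled independently for pollen and stigma. A pollination
fails when some haplotype is expressed in the donor's pollen *and* in the
receptor's stigma (set-intersection rule).

Out of scope by design: phylogenetic tree building and sequence-class
assignment (class tags A/B/C are inputs), codon-model selection tests
(dN/dS site models), paternity assignment (cohort membership is taken as
given), and multi-generation population dynamics.

## Phasing

For a parent P of a cohort, a label is *informative* when P carries it, it
is typable in progeny, and the other parent does not carry it; labels
carried by both parents are treated as missing data for both parents'
transmission vectors rather than attributed by guesswork. Transmission
vectors are boolean over the cohort's observed offspring label
combinations. Clustering is by exact pattern identity:

* two complementary groups → the parent's two haplotypes;
* one group → one visible haplotype (the other may carry no informative
  label), or a possibly homozygous parent when the pattern is all-true;
* an all-true label alongside two complementary groups → that label is
  shared by both haplotypes and is attached to both;
* any other configuration violates diploidy and flags the cohort as
  inconsistent — evidence from it is ignored, never forced.

Pairs co-transmitted in any consistent cohort get support tier
`cosegregation`; a pair co-clustered in one cohort and separated in another
is a hard error naming both cohorts. Pairs never tested in a cohort are
accepted at tier `f0_association_only` when perfectly associated in the
parental panel (identical carrier sets, co-occurring at least once). This
tier is what supports pairs involving progeny-untypable labels.

Genotype assignment covers each individual's label set with exactly one or
two catalog haplotypes; a shared label is disambiguated by which partner
labels are present. A single-haplotype cover yields a *putative*
homozygote; it is upgraded to *confirmed* structurally when the individual
parents a cohort with at most two observed genotype classes, while the
statistical confirmation (0.5/0.5 conformity and absence of a third class)
is the segregation module's test. A residually ambiguous cover raises
rather than guessing.

One identifiability gap is detected explicitly: a typable singleton label
`z` whose carriers are all carriers of a pair member `x`, with no cohort
ever separating the two, is equally well explained by a second `x`-sharing
haplotype `{x, z}`. `phase_dataset` raises on such designs by default
(`strict_ambiguity=False` commits to the singleton catalog). When the
candidate partner is untypable in progeny no cohort could ever resolve the
question; the singleton call is then the standard parsimonious convention
and no flag is raised.

## Segregation test

Cohorts are classified from the parental genotypes: case 1 (het × het,
four classes at 1/4) or case 2 (one putative/confirmed homozygote and at
most two observed classes; two classes at 1/2). Both parents homozygous is
outside the supported scheme and raises. The null distribution of class
counts for cohort size n is simulated as `reps` multinomial draws
(default reps = 100,000). Each expected class receives a one-sided
empirical tail probability in the direction of its observed deviation
(upper tail at exact expectation), with the add-one correction
p = (1 + #{as-or-more-extreme simulated counts}) / (reps + 1), so p is
never zero. A class is flagged at p < alpha (default 0.05); no
multiple-testing correction is applied across classes or cohorts, and
unobserved expected classes are tested like any other (lower tail).
Offspring in combinations outside the expected classes count as unexpected
genotypes and break conformity; for case 2 a zero count of unexpected
genotypes is what rejects the more-than-two-genotypes alternative. The
tail convention and threshold reproduce the reference dataset's published
pattern (eight of ten het × het cohorts conforming; the two deviating ones
flagged for one and for two classes respectively).

Seeding: the default seed is the fixed documented constant 20131223;
`batch_test` derives one child stream per cohort from a single
`SeedSequence`, so results are reproducible and independent of cohort
order-of-evaluation details.

Calibration: the empirical tail is an unbiased estimate of the exact
binomial marginal of the multinomial. The suite checks agreement for every
cohort size 5–50 and every count at a per-point tolerance of
`3·sqrt(p̃(1−p̃)/reps) + 1/(reps+1)` with `p̃ = max(p_mc, p_exact)` — the
add-one estimator is floored at 1/(reps+1), so an exact-tail-based
standard error degenerates in the far tail. Because ~2,800 comparisons are
made, a correct estimator still exceeds a 3-sigma band at a few points by
chance; agreement is therefore asserted jointly (at most 23 exceedances,
three times the count expected under correctness, and no deviation beyond
twice the tolerance). A systematic error — wrong tail direction, off-by-one
counting, biased sampling — produces hundreds of exceedances and fails.

## Dominance inference

Crosses are first consolidated per ordered (donor genotype, receptor
genotype) pair, merging replicates and different individuals with the same
genotype. The default policy is strict: any disagreement makes the pair
`conflicting`, which is reported and excluded from inference (observed
compatibility differences between same-genotype plants are thereby
surfaced, not averaged away). A majority policy is available and is what
makes replicated noisy diallels usable: with failure rate f and leakage
rate l per pollination, the majority of three replicates errs at
3e²(1−e)+e³ < e for either error rate e ∈ {f, l}.

Expression states live per (genotype, organ, haplotype) — not globally per
haplotype, because recessivity is genotype-contextual. Two rules propagate
to a fixed point: (i) for an incompatible cross, among shared haplotypes
not yet silenced on either relevant side, a *unique* viable candidate is
called expressed in the donor's pollen and the receptor's stigma (for
homozygotes the genotype set has one element, so this also grounds the
recursion); (ii) for a compatible cross, a shared haplotype known expressed
in the receptor's stigma is silenced in the donor's pollen, and mirrored.
States move monotonically unknown → expressed/silenced → conflicting, so
the iteration terminates; no rule ever converts expressed to silenced
directly — contradictory derivations become `conflicting` and are listed.
Evidence is used only in the direction observed; non-reciprocal
incompatibility is never symmetrized. Remaining unknowns are `ambiguous`.

Prediction: incompatible iff definitely-expressed pollen and stigma sets
intersect; compatible iff even counting every ambiguous haplotype as
expressed the sets cannot intersect; otherwise undetermined. This matches
exhaustive enumeration over all resolutions of the ambiguous states
(property-tested over all genotype pairs from four haplotypes).

Aggregation: within a heterozygote and organ, expressed + silenced →
dominance edge, expressed + expressed → codominance; edges are summarized
per organ with their supporting genotype and cycles in the aggregate graph
are reported, not resolved.

## Diversity

Nei–Gojobori unweighted pathway counting, the default of the standard
desktop tools for these statistics. Sites: each of a codon's nine
single-base changes weighs 1/3 site, classified by the genetic code
(NCBI table 1 by default, overridable); changes to stop codons are
excluded, so a codon's site total is 3 minus the excluded fraction.
Differences: per codon pair, the synonymous/nonsynonymous step counts are
averaged over all k! minimal pathways that avoid stop codons; if every
pathway is blocked the codon pair is dropped entirely. Codons with gaps,
Ns or stops in either sequence of a pair are excluded pairwise
(complete-codon deletion); the reported n_sites is the minimum retained
nucleotide count over pairs. π_S (π_N) is the mean over unordered pairs of
syn (nonsyn) differences per syn (nonsyn) site. Values are raw proportions
by default; a per-pair Jukes–Cantor correction is optional because the
desktop-tool option used for the reference values is not recorded. The
per-column variability table counts distinct residues per amino-acid
column (gap/N codons masked) with named 1-based inclusive region overlays.

## Simulator

The generator's defaults are the study conditions of the reference design:
13 haplotypes of which 8 carry linked label pairs, optionally one shared
label (only allowed with ≥4 haplotypes, to keep designs identifiable),
class-A fraction 5/13, 21 individuals with homozygote probability 2/21,
the observed cohort sizes (7, 13, 5, 7, 21, 7, 6, 16, 14, 30, 30, 50, 14),
pollination failure 0.29 (so 71% of compatible controls fruit) and SI
leakage 0.09. Dominance per organ is `codominant`, `linear` (a random
strict order) or `class_levels` (class A silences class B, codominance
within class — the reference system's tendency); the default is codominant
stigma with class-level pollen. Offspring genotypes are purely Mendelian
with no SI filtering inside a compatible cross, because all pollen from
one donor shares a single sporophytic phenotype. Untypable labels are
masked in cohort observations only, never in the parental matrix,
mirroring how progeny typing loses markers the parental sequencing had.
The first assignment pass guarantees every haplotype at least one carrier.
Every emitted observation is reproducible from the ground truth and seed.

What the simulator does not emulate: genotyping error in the presence
matrix, partial typing, pollen contamination in cohorts (every sibship has
exactly the two stated parents), and multi-generation allele-frequency
dynamics. Recovery results on simulated data therefore show correctness of
the inference logic under the stated noise model, not robustness to typing
artefacts; on real data the strict consolidation policy and the
inconsistency/ambiguity flags are the guard rails.

## Test problem sizes

The recovery property uses 200 random designs with 4–8 haplotypes, twice
as many individuals as haplotypes, one 25-offspring cohort per individual
and a full noise-free diallel; the noise comparison uses a 40-individual
diallel (1,600 ordered pairs) at 3 replicates. The Monte-Carlo calibration
sweep covers n = 5..50 for both case expectations at reps = 100,000. These
sizes were chosen to estimate every rate to within a few percent while
keeping the default suite fast.
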