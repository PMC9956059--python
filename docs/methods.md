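# Methods

## The screening model

`crossscreen` implements a per-site Mendelian-consistency screen for a
two-breed introgression design. One breed (the "founder" breed, e.g. purebred
Zhedong geese) is resequenced together with F2 and F3 hybrid offspring from a
cross against a second breed (e.g. Zi geese) whose own founders were not
sequenced. At a biallelic SNP, write A for the allele fixed in the sequenced
founders and B for the other allele. If the founder breed is truly fixed for
A and B entered the pedigree only through the other breed, then under
Mendelian transmission an F2 or F3 bird can be A/A or A/B — but in the
screened pattern it is never B/B. The screen therefore keeps a site when:

1. the site is biallelic;
2. the sequenced founders are uniformly homozygous for one allele A
   (assessed over non-missing calls, with at most `max_founder_missing`
   missing calls, default 0);
3. no non-missing F2 or F3 genotype is B/B;
4. at least one offspring is A/B (`require_segregation`, default on: a site
   where every bird is A/A carries no information about the cross);
5. each offspring group has at most `max_offspring_missing` missing calls
   (default: group size − 1, i.e. at least one informative call per group).

Every rejected site gets exactly one reason code, assigned in the fixed
precedence order NON_BIALLELIC → FOUNDER_MISSING_EXCESS →
FOUNDER_NOT_HOMOZYGOUS → OFFSPRING_HOM_ALT → NOT_SEGREGATING →
OFFSPRING_MISSING_EXCESS, so decisions are reproducible and tallies
partition the input. Two deliberate symmetries: genotypes are unordered
(0/1 ≡ 1/0), and A is defined by the founder group, never by which allele is
REF in the VCF — relabelling REF/ALT cannot change a decision.

The statistical weakness of the design is acknowledged rather than hidden:
with five birds per group the pattern arises by chance at many segregating
sites, so the screen is a candidate generator, not a test with controlled
error rates. `require_segregation` and the missing-call caps are policy
flags precisely because the original screening rule is underspecified on
those points; both readings are runnable.

## The synthetic cross generator

No genotype data from the motivating design are publicly deposited, so the
package ships a simulator whose output has the statistical structure the
screen assumes, and all quantitative claims in the test suite are claims
about this generator.

Pedigree. ZD and ZI founder populations (`samples_per_group + 2` each,
so the sequenced founders are a subset of a slightly larger breeding pool),
6 F1 from ZD × ZI matings, and `samples_per_group + 3` each of F2 (F1 × F1)
and F3 (F2 × F2), mated round-robin with distinct parents. Five birds per
sequenced group (founder/C, F2/B, F3/O — the prefixes mirror the design's
sample naming) is the default, matching a five-birds-per-group sampling
scheme.

Sites are independent (free recombination, no linkage map): the screen is
per-site, so linkage would add nothing the tests could detect; linkage
analysis is explicitly out of scope.

Candidate sites (default 60 of 10,000) are fixed A in every ZD founder and
B in every ZI founder. F2 intercross segregation still produces B/B with
probability ¼ per offspring, so the planted *pattern* is enforced by
per-site rejection sampling of the Mendelian transmissions: a candidate
site's gamete draws are redrawn (cap: `rejection_cap`, default 1,000, then
an error) until the sequenced sets show founders homozygous A, no offspring
B/B, and at least one heterozygote. The heterozygote requirement is part of
the conditioning so that with zero noise the screen (with its default
segregation policy) recovers every planted site.

Background sites segregate within the ZD founder pool: a per-site allele
frequency is drawn uniformly from [0.2, 0.8] (configurable) and both breeds
get Hardy–Weinberg genotypes at that frequency. Each background site is
conditioned, by the same per-site rejection, on *violating* the pattern on
the clean sequenced set (a founder heterozygote or mixed homozygotes, or an
offspring homozygous for the non-founder allele) — so with zero noise the
screen's false-positive set is empty by construction, under either
segregation policy. The frequency band keeps background sites informative;
at its edges a site can be one genotype away from conforming, which is what
makes the noisy-recovery experiment non-trivial.

Noise. After breeding, each emitted genotype is independently set missing
with `missing_rate`, else replaced with probability `genotype_error_rate`
by a uniformly chosen different diploid genotype. This is an observation
model on called genotypes; depth- or allele-balance-dependent calling error
is deliberately out of scope.

Genome layout. Sites are spaced 60 bp apart on `n_chromosomes` scaffolds of
random sequence. One intronless CDS per scaffold covers ≈ `cds_fraction`
(default 0.3) of its sites, padded to a codon multiple, with random strand.
The reference sequence makes no open-reading-frame promise: a reference
codon may be a stop, so stop_lost/stop_gained effects occur naturally. The
ZD allele is assigned to REF or ALT by a fair coin per site, so nothing
downstream can lean on REF labelling.

Determinism. One integer seed drives four sub-streams (founders, breeding
and rejection, noise, layout) spawned in fixed order from a
`numpy.random.SeedSequence`; identical configurations give byte-identical
emitted files.

What passing tests on this generator do **not** show about real data:
robustness to linkage between sites, to population structure or relatedness
beyond the modelled pedigree, to multiallelic or indel variation, to
depth-dependent genotyping error, or to misassigned group membership.

## Effect annotation

The annotator handles exactly the narrowing chain's needs: single-base
substitutions against validated gene models (CDS intervals 1-based
inclusive, non-overlapping, total length divisible by 3). A site is CDS,
non_coding (inside a model's span but between CDS intervals) or intergenic.
For CDS sites the genomic position maps to a spliced-CDS coordinate
(reverse-complemented on −strand models), the codon is mutated and both
codons are translated with the standard genetic code (NCBI table 1 — the
appropriate table for bird nuclear CDS; the table is a single constant and
could be swapped, but no alternative is wired up). Effect classes are a pure
function of the residue pair: equal non-Ter → synonymous; Ter→Ter →
stop_retained; non-Ter→Ter → stop_gained; Ter→non-Ter → stop_lost; a change
at residue 1 Met → start_lost; anything else missense. "Exonic" is
operationalised as CDS overlap; the toy models have no UTRs.

HGVS handling: the parser accepts both "c.349G>T" and the spaced dialect
"c.652A > G" seen in published tables; emission always uses the compact
form. A coding position and residue number are consistent when
residue = ((pos − 1) div 3) + 1; the 39-row packaged candidate table is a
parse-and-consistency regression suite, and classifying its protein changes
strictly yields exactly one non-missense row (a Ter→Ter stop-retained
change) — the table's own caption counts all 39 as missense, and the
package reports both numbers rather than resolving the discrepancy.

## Narrowing, enrichment, QC

`narrow_candidates` stages the sets: screen passes → ∩ CDS → ∩ missense,
with a per-scaffold distribution of stage 1 and an effect-class tally of
stage 2. The join between decisions and effects must be exact; orphans on
either side raise an error listing offending keys.

Enrichment is a gene-level hypergeometric over-representation test: the
universe is genes, not SNPs, so several candidate SNPs in one gene count
once (avoiding pseudo-replication). For a term with K of N universe genes
and k of n candidate genes, p = P[X ≥ k], X ~ Hypergeometric(N, K, n),
computed via `scipy.stats.hypergeom.sf`; Benjamini–Hochberg q-values are
reported alongside raw p (the step-up adjustment is implemented in-package
and cross-checked against statsmodels in the tests). The universe is an
argument of the analysis rather than a field of each term annotation — one
analysis has one universe. Reports list terms ascending by p, ties broken
by term id; the conventional report length is the top 25.

QC: per-sample unaligned and uniquely-aligned percentages are exact
rationals (`Fraction`), so unaligned% + uniquely% + residual% = 100 holds
identically before any rounding. Formatting rounds half-even at six
significant figures and strips trailing zeros — the policy that reproduces
every percentage in the packaged sequencing-statistics table, adopted as a
formatting convention, not arithmetic. The quality gate is Q30 ≥ 80%
(inclusive); a clean-bases threshold is available only when a read length
is supplied, since clean gigabases are not computable from read counts
alone.

## Pipeline

`crossscreen run --config run.yaml` executes simulate → screen → annotate →
narrow → enrich → qc. The run manifest records the package version, a
SHA-256 hash of the fully-resolved config, the seed, per-stage tallies
(sites, screen passes, exonic, missense — the pipeline's narrowing chain)
and a checksum of every output file; no timestamps are written, so a rerun
of the same config is byte-identical. The enrichment stage of the demo run
uses a seeded synthetic term layer over the simulated genes plus padding
genes (the annotation table is user-supplied in real use); the QC stage
demonstrates the arithmetic on the packaged fixture. Exit codes: 0 success,
2 configuration error, 3 stage failure.

## Problem sizes and numerical choices

The bundled demo uses 1,500 sites with 40 planted candidates; the recovery
experiments in the test suite use 10,000 sites with 60 planted candidates
and five samples per group, with the noisy variant averaged over seeds
0–19 at a 1% genotype error rate. The screen-rule equivalence check
enumerates all 9,261 unordered per-group genotype configurations (the
order-free collapse of 3^15 ordered assignments; order-invariance is its
own test). Hypergeometric correctness is checked against exact rational
summation on every instance with N ≤ 20 and against one-sided Fisher tests
at 10⁻¹² relative tolerance on random larger instances. Monte Carlo
assertions use 3-standard-error bands throughout.

## Known limitations

- The screen is a filter, not an inference procedure: no error-rate
  control, no explicit model of genotyping uncertainty.
- The simulator's guarantees are conditional constructions (rejection
  sampling), not emergent properties; they define the test conditions
  rather than mimic any particular empirical dataset.
- The annotator covers substitutions only — no indels, splice sites,
  regulatory features or UTR annotation.
- Enrichment assumes a user-supplied annotation table; no ontology
  topology, term relationships or real GO/KEGG retrieval.
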