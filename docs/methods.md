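# Methods

## The inference problem

A haplotype shared between present-day humans and Neandertals can have two
origins: gene flow during admixture (~2,000 generations ago), or incomplete
lineage sorting (ILS) — an ancestral polymorphism that persisted through
the population split.  The package combines three lines of evidence for a
single candidate region: (i) the haplotype is long and tightly linked,
(ii) it is too long to be a plausible ILS remnant given the local
recombination rate, and (iii) its sequence falls inside the archaic clade
of a rooted phylogeny.  Absence from a non-admixed (sub-Saharan) population
is corroborating evidence carried by the frequency table.

## Linkage disequilibrium and the haplotype block

r² is computed from **phased haplotype counts**, not genotype correlation:
`D = p_AB − p_A p_B`, `r² = D² / (p_A(1−p_A) p_B(1−p_B))`.  Haplotypes with
a missing allele at either site are excluded pairwise; a site monomorphic
after exclusion has *undefined* LD, which is an error distinct from r² = 0.
LD is pooled across all samples by default (population subsets are
available through the group-aware frequency interface).

The block around an index variant is the min–max envelope of all sites
whose r² with the index reaches the cutoff (default 0.8, exposed; at that
value strict vs non-strict inequality is immaterial in practice — we use
≥).  No contiguity is required.  Block length is `span_end − span_start`
(not +1), matching the usual span convention for printed coordinates.

## ILS survival test

Expected surviving length of an ancestral segment:

    L_expected = 1 / (r_bp · G_total),  r_bp = rate[cM/Mb] × 1e-8

with `G_total = branch_factor × split_time / generation_time`.  Defaults:
split_time 550,000 y, generation_time 29 y, branch_factor 2 (the segment
must escape recombination along both the modern and the archaic branch).
All three are flags — no published parameter set is baked in, and the
report always carries the parameters next to the p-value, plus a
sensitivity sweep over split times (400/550/700 ky).  The tract around a
focal point extends an exponential distance each way, so total length is
gamma(shape 2, mean 2·L_expected) and

    p = P(length ≥ ℓ) = (1 + x) e^{−x},  x = ℓ / L_expected.

The local rate is the difference of linearly interpolated cumulative cM at
the region endpoints divided by the span in Mb; no extrapolation beyond
the map's support, and no Haldane/Kosambi map function (negligible at
sub-cM scales).  In the orchestrated run the rate is taken over the whole
analysis region, which also keeps degenerate single-site blocks
well-defined.

## Phylogeny

Sites: modern segregating biallelic SNVs in the region with a homozygous
variant call in a chosen reference archaic (default Vindija); heterozygous
or missing reference calls exclude the site.  Taxa: one (configurable)
carrier haplotype, N outgroup-population haplotypes (default five, one per
sample), each archaic genome pseudo-haploidized (hom calls give the allele;
het calls are resolved by one uniform draw from the run seed; missing → N),
and the ancestral sequence, which roots the tree.

Distances are Tamura–Nei (1993) with base frequencies pooled once over the
whole alignment (per-pair frequencies would make distances non-comparable
across pairs).  Columns missing in >50% of taxa are dropped up front;
remaining missing cells are deleted pairwise.  A non-positive logarithm
argument (saturation) is an error: these alignments are closely related
and a silent fallback would mask a data problem.

Trees are neighbor-joining — deterministic, with Q-criterion ties broken
by first row-major minimum, and negative branch lengths clamped to zero
with the deficit logged.  NJ is exact on additive matrices, which the test
suite exercises directly; dendropy's independent NJ implementation serves
as a cross-check on noisy matrices, and the TN93 formula is cross-checked
against an independent evaluation and R ape's `dist.dna`.  (The original
balanced-minimum-evolution refinement of distance trees differs from NJ
only by local rearrangements; at ~11 taxa with a strong signal the
topologies coincide, and NJ is fully specifiable.)

Bootstrap: B column resamples of the selected-site alignment (replicate r
seeded with master+r, so runs are reproducible and order-independent);
each internal edge of the full-data tree counts the replicates containing
its bipartition.  A degenerate replicate — all-constant resample or
saturated distances — contributes a star (no bipartitions) and is logged.
Rooting places the root on the branch subtending the ancestral leaf,
splitting its length equally; supports are re-attached by bipartition
identity, which rooting does not change.

## Synthetic data generator

The generator plants a known introgression history into exactly the file
formats the pipeline reads.  It is deliberately not a coalescent simulator:
it endows the data with the three properties the inference uses — deep
archaic divergence, a long shared tract in carriers, absence from the
outgroup — and nothing else.

Sites fall into four classes.  *Archaic-derived* sites (a Poisson count
with mean `mutation_rate × divergence_generations × region_length`) are
fixed differences on the archaic lineage; `divergence_generations`
(default 27,500 ≈ 800 ky at 29 y/generation) exceeds the population split
because sequence divergence includes coalescence in the common ancestral
population.  *Shared* sites (5% of the rest) are ancient polymorphisms
fixed in archaics and common in moderns.  *Reference-derived* sites (70%)
model the fact that the reference assembly is itself a modern haplotype:
REF is the modern-derived allele, ALT the ancestral one, and archaics are
homozygous ALT.  The remainder are modern-derived background
polymorphisms.  Background variation is unlinked, with alt frequencies
uniform on (0.8, 0.98) for the common classes and (0.05, 0.95) otherwise;
derived bases are uniform over the three alternatives.  These choices are
calibrated so that a selected-site alignment behaves like its real
counterpart: pairwise divergences stay inside the substitution model's
validity even in bootstrap resamples, and the ancestral sequence is closer
to the non-admixed moderns than to the archaics.  Without the shared and
reference-derived classes, every selected column would separate carriers
from everyone else — a 100%-divergent alignment no distance model
tolerates, and not a feature of real data.

One tract is realized per dataset: centered at `tract_center`, with two
independent exponential half-lengths of mean
`1/(recomb_rate_per_bp × admix_generations)`, clipped to the region.  Every
carrier (each recipient haplotype independently with probability
`admix_fraction`) carries that same tract — it represents the surviving
common core of the introgressed haplotype, which is what an r²-based block
can detect.  Per-carrier private tract extensions are not modeled: sites on
them would be carried by haplotype subsets and could not reach the r²
cutoff, so they would add noise without signal.  The exponential erosion
model intentionally matches the ILS module's survival model, making
parameter recovery a closed loop — passing tests demonstrate internal
consistency of the chain, not the realism of either model.

Archaic individuals are diploids from the archaic pool with configurable
per-site heterozygosity (2%) and missingness (1%).  Same seed ⇒
byte-identical output files.

What the generator does **not** emulate: background LD among neutral
variants, mutation since admixture on the introgressed tract, population
structure within groups, allele-frequency spectra, genotyping error, and
coalescent variance in the archaic pool.  Results on synthetic data
therefore validate the pipeline's logic and numerics, not its behaviour on
every pathology of real cohorts.

## Defaults and problem sizes

| parameter | default | meaning |
|---|---|---|
| region_length | 300,000 bp | candidate region span |
| n_sites | 400 | segregating SNVs in the region |
| n_recipient / n_outgroup | 60 / 30 diploids | recipient (EUR-like) and outgroup (AFR-like) samples |
| admix_fraction | 0.1 | introgressed-haplotype frequency among recipient haplotypes |
| admix_generations | 2,000 | time since gene flow |
| split_generations | 19,000 (~550 ky) | modern–archaic population split |
| divergence_generations | 27,500 (~800 ky) | modern–archaic sequence divergence |
| mutation_rate | 1.25e-8 /bp/gen | human germline point rate |
| recomb_rate | 0.27 cM/Mb | local rate of the motivating region |
| r² threshold | 0.8 | block membership cutoff |
| bootstrap B | 1000 (tests/acceptance use 200) | replicate count |

Sample sizes and the 200-replicate bootstrap used in the automated checks
are scaled-down choices that keep the full chain interactive while leaving
all test margins wide; B is a flag wherever it appears.

## Numerical and degenerate-input conventions

Coordinates are 1-based inclusive internally (BED output converts to
0-based half-open).  Multi-allelic and indel VCF records are dropped, never
split, and counted.  Unphased heterozygotes are an error naming the site;
unphased homozygotes are accepted (their phase is unambiguous).  Archaic
records are matched on exact (chrom, pos, ref, alt); allele-swapped records
are excluded with a warning, never flipped.  Missing archaic calls stay
missing and are deleted pairwise downstream.  r² is clamped to [0,1]
against floating-point spill and computed in a grouping that is exactly
symmetric in its arguments.  Genetic maps must have ≥2 rows, strictly
increasing positions and non-decreasing cM; violations report the line
number.

## Known limitations

- One candidate region at a time; this is not a genome-wide introgression
  scanner, and admixture *dating* from tract lengths is out of scope.
- The ILS p-value is a survival probability under an explicit parameter
  trio, not a calibrated frequentist test; the report prints the
  parameters and a sensitivity sweep rather than a single "the" p-value.
- TN93 distances on SNV-only alignments are per-selected-column, not
  per-genomic-bp; branch lengths are comparable within a tree only.
- Archaic genotypes are taken as called; no contamination or damage
  modeling, and no imputation.
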