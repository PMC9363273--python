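# archhap

Archaic-introgression inference for a single candidate haplotype.

Some long haplotypes in present-day non-African genomes entered our gene
pool through admixture with Neandertals roughly 2,000 generations ago.  The
motivating case is pharmacogenetic: the *CYP2C8\*3* and *CYP2C9\*2*
star alleles on chromosome 10 — variants that slow the metabolism of
warfarin, phenytoin, ibuprofen and other drugs — ride together on a ~300 kb
haplotype (chr10:96,537,863–96,851,277, hg19) that is carried homozygously
by the high-coverage Neandertal genomes and absent from sub-Saharan
populations.  `archhap` packages the complete chain of evidence used to
establish such an origin for any candidate region:

1. **LD block delineation** (`archhap.ld`) — pairwise r² from phased
   haplotypes, `r² = D²/(p_A(1−p_A)p_B(1−p_B))` with `D = p_AB − p_A p_B`,
   and the min–max envelope of all sites with r² ≥ 0.8 against an index
   variant; per-super-population allele frequencies.
2. **Archaic matching** (`archhap.archaic`) — genotype summaries and
   carrier verdicts for Neandertal/Denisovan genomes at the defining
   variants; selection of phylogeny sites (modern segregating SNVs called
   homozygous-variant in a reference archaic, e.g. Vindija); assembly of a
   nucleotide alignment of modern haplotypes, pseudo-haploidized archaics
   and the ancestral sequence.
3. **Incomplete-lineage-sorting test** (`archhap.ils`) — an ancestral
   segment surviving recombination for `G = 2·T_split/T_gen` generations has
   expected length `L = 1/(r·G)` (r in per-bp per-generation units,
   1 cM/Mb = 10⁻⁸); the surviving tract around a focal variant is the sum of
   two exponentials, so `P(length ≥ ℓ) = (1+x)e^{−x}` with `x = ℓ/L`.  A
   small p rejects ILS in favour of gene flow.  The local r comes from
   linear interpolation of a cumulative genetic map.
4. **Phylogeny** (`archhap.phylo`) — Tamura–Nei (TN93) distances,
   neighbor-joining, column-resampling bootstrap, rooting on the ancestral
   sequence.
5. **Synthetic data** (`archhap.synthetic_data`) — a generator that plants
   an introgressed tract with known truth into phased VCF + panel +
   archaic-call + ancestral + genetic-map files, so the whole chain is
   testable without downloads.

`archhap.pipeline.run_full_analysis` (CLI: `archhap run`) chains all stages
into one reproducible report.

## Worked example

Simulate the default study conditions — a 300 kb region, 400 SNVs, an
introgressed haplotype at frequency 0.1 in a 60-sample recipient population
(plus a 30-sample non-admixed outgroup), admixture 2,000 generations ago,
recombination 0.27 cM/Mb — then run the full analysis:

```python
from archhap import SimConfig, simulate_dataset, RunConfig, run_full_analysis

ds = simulate_dataset(SimConfig(seed=1), out_dir="sim/")
cfg = RunConfig(
    vcf="sim/modern.vcf", panel="sim/panel.tsv", archaic=["sim/archaic.tsv"],
    ancestral="sim/ancestral.tsv", genetic_map="sim/genetic_map.tsv",
    region="chrS:1-300000", index=ds.truth.index_rsid,
    outgroup_pop="YRI", bootstrap=200, seed=7,
)
report = run_full_analysis(cfg)
print(report["block"]["length"], report["ils"]["p_value"],
      report["phylogeny"]["carrier_plus_archaic_support"])
```

prints

```
76617 0.0034596075086887257 200
```

meaning: the LD block around the index variant spans 76,617 bp (covering
91% of the true planted tract, 96,940–180,968 bp); a haplotype that long
has probability 3.5×10⁻³ of surviving recombination since the
modern–Neandertal split under the default parameters (split 550 ky,
29 y/generation, both branches), so ILS is rejected; and in all 200
bootstrap replicates the carrier haplotype forms a clade with the four
archaic genomes to the exclusion of the outgroup haplotypes and the
ancestral root.

The same stages run from the shell:

```sh
archhap simulate --out sim/ --seed 1
archhap ld   --vcf sim/modern.vcf --region chrS:1-300000 --index simrs196
archhap ils  --map sim/genetic_map.tsv --region chrS:1-300000 --length 76617
archhap run  --config run.json
```

For a real-data run, point `RunConfig` at a phased 1000 Genomes VCF slice,
a sample panel, archaic VCFs, an Ensembl ancestral-allele track and a
deCODE-style genetic map, with e.g. `region="chr10:96537863-96851277"`,
`index="rs1799853"` and `defining=["rs11572080", "rs10509681", "rs1799853"]`.

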