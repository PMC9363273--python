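"""Synthetic datasets with a planted archaic-introgression history.

The generator produces every input the pipeline reads — phased VCF,
population panel, archaic genotype table, ancestral-allele track, genetic
map — plus the ground truth, so the whole inference chain is testable
without any downloads.

Generative model (deliberately simpler than a coalescent; see the methods
note):

1. Site positions are drawn uniformly without replacement; each site gets
   an ancestral base and a derived base drawn uniformly from the three
   alternatives.
2. Sites fall into four classes.  *Archaic-derived* sites — a
   Poisson(mutation_rate × divergence_generations × region_length) number
   of them — are fixed differences on the archaic lineage: carried by the
   whole archaic pool, absent from the modern background.  *Shared* sites are ancient
   polymorphisms whose derived allele is fixed in archaics and common in
   moderns.  *Reference-derived* sites model the fact that the reference
   assembly is itself a modern haplotype: the REF allele is the
   modern-derived one, the ALT is ancestral, and archaics are homozygous
   ALT (ancestral).  The rest are *modern-derived* background
   polymorphisms absent from archaics.  All background variation is
   unlinked (independent across sites and haplotypes).  Without the
   shared and reference-derived classes a selected-site alignment would
   be implausibly divergent (every column separating carriers from
   everyone else), which no substitution model tolerates.
3. One introgressed tract is realized per dataset: centered at
   tract_center, its two half-lengths are independent exponentials with
   mean 1/(recomb_rate_per_bp × admix_generations) — the surviving common
   core of the introgressed haplotype after admix_generations of
   recombination erosion.  Each recipient-population haplotype is a
   carrier with probability admix_fraction; carriers all share the tract:
   inside it they carry the archaic-derived alleles (and no background
   ones), outside it they are ordinary background haplotypes.
4. Archaic individuals are diploids from the archaic pool: homozygous
   derived at archaic-derived sites, homozygous ancestral at background
   sites, with configurable per-site heterozygosity and missingness.
5. The outgroup population carries no tract, so planted archaic-derived
   alleles have frequency 0 there.

Same seed ⇒ byte-identical emitted files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genomic_io import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    ArchaicGenotypeTable,
    GeneticMap,
    HaplotypeMatrix,
    PopulationPanel,
    VariantSite,
)

CM_PER_MB_TO_PER_BP = 1e-8

DEFAULT_ARCHAIC_NAMES = ("Vindija", "Chagyrskaya", "Altai", "Denisova")


@dataclass
class SimConfig:
    """Parameters of the planted-introgression simulation.

    Defaults emulate the study system: a ~300 kb region, an introgressed
    haplotype at ~10% frequency in the recipient population, admixture
    ~2,000 generations ago, a deep archaic split (~19,000 generations ≈
    550 ky at 29 y/generation) and a local recombination rate of
    0.27 cM/Mb.  ``divergence_generations`` (~27,500 ≈ 800 ky) governs how
    many fixed differences separate the archaic and modern pools: sequence
    divergence predates the population split by the coalescent time in the
    common ancestral population, so it exceeds ``split_generations``.

    The class fractions and frequency ranges are set so the selected-site
    alignment behaves like its real counterpart: pairwise divergences stay
    inside the substitution model's validity, and the ancestral sequence
    is closer to the non-admixed moderns than to the archaics.
    """

    region_length: int = 300_000
    n_sites: int = 400
    n_recipient: int = 60  # diploid samples in the recipient population
    n_outgroup: int = 30  # diploid samples in the non-admixed outgroup
    recipient_pop: tuple[str, str] = ("CEU", "EUR")  # (pop, super_pop)
    outgroup_pop: tuple[str, str] = ("YRI", "AFR")
    n_archaic: int = 4
    split_generations: int = 19_000
    divergence_generations: int = 27_500
    admix_generations: int = 2_000
    admix_fraction: float = 0.1
    mutation_rate: float = 1.25e-8  # per bp per generation
    recomb_rate: float = 0.27  # cM/Mb, uniform
    tract_center: int = 150_000
    shared_fraction: float = 0.05  # of non-archaic sites: ancient shared polymorphisms
    ref_derived_fraction: float = 0.70  # of non-archaic sites: REF is the derived allele
    common_freq_range: tuple[float, float] = (0.8, 0.98)  # alt freq, shared/ref-derived
    background_freq_range: tuple[float, float] = (0.05, 0.95)  # alt freq, modern-derived
    archaic_het_rate: float = 0.02
    archaic_missing_rate: float = 0.01
    chrom: str = "chrS"
    seed: int = 1

    def __post_init__(self) -> None:
        if not (0 <= self.admix_fraction <= 1):
            raise ValueError("admix_fraction must be in [0, 1]")
        if self.admix_generations >= self.split_generations:
            raise ValueError("admixture must postdate the archaic split")
        if self.divergence_generations < self.split_generations:
            raise ValueError("sequence divergence cannot predate the population split")
        if min(self.mutation_rate, self.recomb_rate) <= 0:
            raise ValueError("rates must be positive")
        if not (1 <= self.tract_center <= self.region_length):
            raise ValueError("tract_center must lie inside the region")
        if self.n_sites < 2 or self.n_sites > self.region_length:
            raise ValueError("n_sites must be in [2, region_length]")
        if self.shared_fraction + self.ref_derived_fraction > 1:
            raise ValueError("shared_fraction + ref_derived_fraction must be <= 1")

    @property
    def archaic_names(self) -> list[str]:
        names = list(DEFAULT_ARCHAIC_NAMES[: self.n_archaic])
        names += [f"Archaic{i + 1}" for i in range(len(names), self.n_archaic)]
        return names

    @classmethod
    def from_json(cls, path: "str | Path") -> "SimConfig":
        raw = json.loads(Path(path).read_text())
        for key in ("recipient_pop", "outgroup_pop", "common_freq_range", "background_freq_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["recipient_pop"] = list(self.recipient_pop)
        d["outgroup_pop"] = list(self.outgroup_pop)
        return d


@dataclass
class SimTruth:
    """Ground truth of one simulated dataset."""

    carrier: dict[tuple[str, int], bool]
    tract: "tuple[int, int] | None"  # shared surviving core (bp, inclusive)
    site_class: dict[int, str]  # pos -> archaic_derived | shared | modern_derived[_ref]
    index_rsid: "str | None"  # suggested index variant for block delineation
    config: SimConfig

    def tract_of(self, sample: str, side: int) -> "tuple[int, int] | None":
        return self.tract if self.carrier[(sample, side)] else None

    @property
    def n_carriers(self) -> int:
        return sum(self.carrier.values())

    def to_dict(self) -> dict:
        return {
            "carrier": {f"{s}/{side}": bool(c) for (s, side), c in self.carrier.items()},
            "tract": list(self.tract) if self.tract else None,
            "site_class": {str(p): c for p, c in self.site_class.items()},
            "index_rsid": self.index_rsid,
            "n_carriers": self.n_carriers,
            "config": self.config.to_dict(),
        }


@dataclass
class SimDataset:
    """In-memory objects plus (optionally) the paths they were written to."""

    sites: list[VariantSite]
    matrix: HaplotypeMatrix
    panel: PopulationPanel
    archaic: ArchaicGenotypeTable
    gmap: GeneticMap
    truth: SimTruth
    paths: dict[str, Path] = field(default_factory=dict)


def draw_tract_half_lengths(
    rate_cm_per_mb: float, generations: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Exponential tract half-lengths, mean 1/(r_bp × generations), in bp."""
    mean = 1.0 / (rate_cm_per_mb * CM_PER_MB_TO_PER_BP * generations)
    return rng.exponential(mean, size=n)


def simulate_dataset(config: SimConfig, out_dir: "str | Path | None" = None) -> SimDataset:
    """Generate one dataset; write the pipeline's input files if out_dir given.

    Emits ``modern.vcf``, ``panel.tsv``, ``archaic.tsv``, ``ancestral.tsv``,
    ``genetic_map.tsv`` and ``truth.json`` into ``out_dir``.
    """
    rng = np.random.default_rng(config.seed)
    L = config.n_sites

    # -- sites, ancestral/derived alleles ---------------------------------
    positions = np.sort(rng.choice(config.region_length, size=L, replace=False)) + 1
    bases = np.array(list("ACGT"))
    anc_idx = rng.integers(4, size=L)
    # derived base: uniform over the three alternatives.  (A transition bias
    # would concentrate divergence into the substitution model's transition
    # terms, which tolerate far less divergence than the transversion term;
    # uniform draws keep selected-site alignments well inside model validity.)
    der_idx = (anc_idx + 1 + rng.integers(3, size=L)) % 4

    # -- site classes ------------------------------------------------------
    mean_stem = config.mutation_rate * config.divergence_generations * config.region_length
    n_archaic_sites = int(min(rng.poisson(mean_stem), L // 2))
    archaic_site_idx = np.sort(rng.choice(L, size=n_archaic_sites, replace=False))
    is_archaic_site = np.zeros(L, dtype=bool)
    is_archaic_site[archaic_site_idx] = True
    u = rng.random(L)
    is_shared = (~is_archaic_site) & (u < config.shared_fraction)
    is_ref_derived = (~is_archaic_site) & (u >= config.shared_fraction) & (
        u < config.shared_fraction + config.ref_derived_fraction
    )
    # VCF coding: REF is the ancestral base except at ref-derived sites,
    # where the reference haplotype carries the modern-derived allele
    ref_idx = np.where(is_ref_derived, der_idx, anc_idx)
    alt_idx = np.where(is_ref_derived, anc_idx, der_idx)
    sites = [
        VariantSite(
            chrom=config.chrom,
            pos=int(positions[j]),
            ref=str(bases[ref_idx[j]]),
            alt=str(bases[alt_idx[j]]),
            rsid=f"simrs{j + 1}",
            ancestral=str(bases[anc_idx[j]]),
        )
        for j in range(L)
    ]

    # archaic pool haplotype and modern background ALT frequencies, ALT-coded
    archaic_pool_state = (is_archaic_site | is_shared | is_ref_derived).astype(np.int8)
    lo_c, hi_c = config.common_freq_range
    lo_b, hi_b = config.background_freq_range
    common = rng.uniform(lo_c, hi_c, size=L)
    rare = rng.uniform(lo_b, hi_b, size=L)
    background_freq = np.where(is_archaic_site, 0.0, np.where(is_shared | is_ref_derived, common, rare))

    # -- modern haplotypes -------------------------------------------------
    recipient_samples = [f"{config.recipient_pop[0]}{i + 1:03d}" for i in range(config.n_recipient)]
    outgroup_samples = [f"{config.outgroup_pop[0]}{i + 1:03d}" for i in range(config.n_outgroup)]
    samples = recipient_samples + outgroup_samples
    hap_ids = [(s, side) for s in samples for side in (1, 2)]
    n_hap = len(hap_ids)
    n_recipient_hap = 2 * config.n_recipient

    data = (rng.random((n_hap, L)) < background_freq[None, :]).astype(np.int8)

    # one shared surviving tract; carriers drawn per recipient haplotype
    e1, e2 = draw_tract_half_lengths(
        config.recomb_rate, config.admix_generations, 2, rng
    )
    tract = (
        max(1, int(config.tract_center - e1)),
        min(config.region_length, int(config.tract_center + e2)),
    )
    carrier_flags = rng.random(n_recipient_hap) < config.admix_fraction
    in_tract = (positions >= tract[0]) & (positions <= tract[1])
    for h in range(n_recipient_hap):
        if carrier_flags[h]:
            data[h, in_tract] = archaic_pool_state[in_tract]

    seg = [(c.min() != c.max()) for c in data.T]
    if not any(seg):
        raise ValueError("configuration yielded 0 segregating sites")

    matrix = HaplotypeMatrix(sites=sites, data=data, haplotype_ids=hap_ids)
    panel = PopulationPanel(
        entries={
            **{s: config.recipient_pop for s in recipient_samples},
            **{s: config.outgroup_pop for s in outgroup_samples},
        }
    )

    # -- archaic diploids --------------------------------------------------
    names = config.archaic_names
    geno = np.tile(np.where(archaic_pool_state == 1, HOM_ALT, HOM_REF).astype(np.int8),
                   (len(names), 1))
    het_mask = rng.random((len(names), L)) < config.archaic_het_rate
    geno[het_mask] = HET
    miss_mask = rng.random((len(names), L)) < config.archaic_missing_rate
    geno[miss_mask] = MISSING
    archaic = ArchaicGenotypeTable(individuals=names, sites=sites, genotypes=geno)

    # -- genetic map (uniform) --------------------------------------------
    map_pos = np.linspace(1, config.region_length, 11).round().astype(int)
    map_cm = config.recomb_rate * (map_pos - 1) / 1e6
    gmap = GeneticMap(pos=map_pos.astype(float), cm=map_cm)

    # -- truth -------------------------------------------------------------
    any_carrier = bool(carrier_flags.any())
    index_rsid = None
    if any_carrier and n_archaic_sites:
        candidates = archaic_site_idx[in_tract[archaic_site_idx]]
        if candidates.size:
            nearest = candidates[np.argmin(np.abs(positions[candidates] - config.tract_center))]
            index_rsid = sites[int(nearest)].rsid
    carrier = {
        hid: (bool(carrier_flags[h]) if h < n_recipient_hap else False)
        for h, hid in enumerate(hap_ids)
    }
    truth = SimTruth(
        carrier=carrier,
        tract=tract if any_carrier else None,
        site_class={
            int(positions[j]): (
                "archaic_derived" if is_archaic_site[j]
                else "shared" if is_shared[j]
                else "modern_derived_ref" if is_ref_derived[j]
                else "modern_derived"
            )
            for j in range(L)
        },
        index_rsid=index_rsid,
        config=config,
    )

    dataset = SimDataset(
        sites=sites, matrix=matrix, panel=panel, archaic=archaic, gmap=gmap, truth=truth
    )
    if out_dir is not None:
        dataset.paths = _write_dataset(dataset, Path(out_dir))
    return dataset


# ---------------------------------------------------------------------------
# file emission (exactly the formats genomic_io reads)
# ---------------------------------------------------------------------------

def _write_dataset(ds: SimDataset, out_dir: Path) -> dict[str, Path]:
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = ds.truth.config
    paths = {
        "vcf": out_dir / "modern.vcf",
        "panel": out_dir / "panel.tsv",
        "archaic": out_dir / "archaic.tsv",
        "ancestral": out_dir / "ancestral.tsv",
        "genetic_map": out_dir / "genetic_map.tsv",
        "truth": out_dir / "truth.json",
    }
    _write_vcf(paths["vcf"], ds.matrix, cfg)
    _write_panel(paths["panel"], ds.panel)
    _write_archaic_tsv(paths["archaic"], ds.archaic)
    _write_ancestral_tsv(paths["ancestral"], ds.sites)
    _write_map_tsv(paths["genetic_map"], ds.gmap)
    paths["truth"].write_text(json.dumps(ds.truth.to_dict(), indent=2, sort_keys=True) + "\n")
    return paths


def _write_vcf(path: Path, matrix: HaplotypeMatrix, cfg: SimConfig) -> None:
    samples = matrix.samples
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={cfg.chrom},length={cfg.region_length}>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    for j, site in enumerate(matrix.sites):
        col = matrix.data[:, j]
        gts = []
        for k in range(len(samples)):
            a, b = col[2 * k], col[2 * k + 1]
            gts.append(f"{'.' if a < 0 else a}|{'.' if b < 0 else b}")
        lines.append(
            f"{site.chrom}\t{site.pos}\t{site.rsid or '.'}\t{site.ref}\t{site.alt}"
            f"\t.\tPASS\t.\tGT\t" + "\t".join(gts)
        )
    path.write_text("\n".join(lines) + "\n")


def _write_panel(path: Path, panel: PopulationPanel) -> None:
    lines = ["sample\tpop\tsuper_pop"]
    lines += [f"{s}\t{p}\t{sp}" for s, (p, sp) in panel.entries.items()]
    path.write_text("\n".join(lines) + "\n")


def _write_archaic_tsv(path: Path, table: ArchaicGenotypeTable) -> None:
    gt_text = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}
    lines = ["chrom\tpos\tref\talt\t" + "\t".join(table.individuals)]
    for j, site in enumerate(table.sites):
        cells = "\t".join(gt_text[int(g)] for g in table.genotypes[:, j])
        lines.append(f"{site.chrom}\t{site.pos}\t{site.ref}\t{site.alt}\t{cells}")
    path.write_text("\n".join(lines) + "\n")


def _write_ancestral_tsv(path: Path, sites: list[VariantSite]) -> None:
    lines = ["pos\tallele"]
    lines += [f"{s.pos}\t{s.ancestral}" for s in sites if s.ancestral]
    path.write_text("\n".join(lines) + "\n")


def _write_map_tsv(path: Path, gmap: GeneticMap) -> None:
    lines = ["pos\tcM"]
    lines += [f"{int(p)}\t{c:.10g}" for p, c in zip(gmap.pos, gmap.cm)]
    path.write_text("\n".join(lines) + "\n")
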