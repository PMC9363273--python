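"""Orchestration of the full analysis: one config in, one report out.

The run mirrors the study design for a single candidate region:

1. ingest phased modern genotypes, panel, archaic calls, ancestral track
   and genetic map;
2. allele frequencies of the defining variants per super-population and
   their pairwise r²;
3. LD block around the index variant (span, length);
4. local recombination rate and the ILS haplotype-length survival test,
   with a split-time sensitivity sweep;
5. archaic genotype summary and carrier verdicts;
6. phylogeny-site selection, alignment assembly, bootstrapped NJ tree
   rooted in the ancestral sequence.

Every random step's seed is recorded in the report; re-running an
identical config yields byte-identical JSON.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import archaic as archaic_mod
from . import genomic_io as gio
from . import ils as ils_mod
from . import ld as ld_mod
from . import phylo as phylo_mod

logger = logging.getLogger("archhap")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    vcf: str
    panel: str
    archaic: list[str]
    ancestral: str
    genetic_map: str
    region: str
    index: str  # rsid or chrom:pos of the index variant
    defining: list[str] = field(default_factory=list)  # defaults to [index]
    ld_threshold: float = 0.8
    split_time: float = ils_mod.DEFAULT_SPLIT_YEARS
    generation_time: float = ils_mod.DEFAULT_GENERATION_YEARS
    branch_factor: int = ils_mod.DEFAULT_BRANCH_FACTOR
    ils_alpha: float = 0.05
    reference_archaic: str = "Vindija"
    outgroup_pop: str = "YRI"
    n_outgroup: int = 5
    carrier_haplotype: "str | None" = None  # "SAMPLE/SIDE"; default: first carrier
    bootstrap: int = 1000
    seed: int = 42
    out_dir: "str | None" = None

    def __post_init__(self) -> None:
        if isinstance(self.archaic, str):
            self.archaic = [self.archaic]
        if not self.defining:
            self.defining = [self.index]
        gio.Region.parse(self.region)  # validate early

    @classmethod
    def from_json(cls, path: "str | Path") -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))


def _stage(name: str):
    def decorator(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as e:
                raise PipelineError(f"stage {name!r}: {e}") from e
        return wrapper
    return decorator


def run_full_analysis(config: RunConfig) -> dict:
    """Run the whole chain; return the report dict (and write outputs if
    ``config.out_dir`` is set: report.json, tree.nwk, block.bed,
    frequencies.tsv, alignment.fasta)."""
    report: dict = {"config": dataclasses.asdict(config)}

    sites, matrix, dropped = _stage("read_phased_vcf")(gio.read_phased_vcf)(
        config.vcf, config.region
    )
    panel = _stage("read_panel")(gio.read_panel)(config.panel)
    _stage("read_ancestral")(gio.read_ancestral)(config.ancestral, sites)
    archaic_table = _stage("read_archaic")(gio.read_archaic)(config.archaic, sites)
    gmap = _stage("read_genetic_map")(gio.read_genetic_map)(config.genetic_map)
    report["inputs"] = {
        "n_sites": len(sites),
        "n_samples": len(matrix.samples),
        "dropped_records": dropped,
        "archaic_individuals": archaic_table.individuals,
    }

    freq = _stage("allele_frequencies")(ld_mod.frequency_table)(
        config.defining, matrix, panel
    )
    report["frequencies"] = {
        "note": "alt-allele frequency per super-population, all samples pooled per group",
        "by_super_population": freq,
    }

    labels, r2 = _stage("ld_matrix")(ld_mod.ld_matrix)(config.defining, matrix)
    report["ld"] = {
        "note": "r^2 from phased haplotypes, all samples pooled",
        "labels": labels,
        "r2": [[round(v, 10) for v in row] for row in r2],
    }

    block = _stage("ld_block")(ld_mod.ld_block)(config.index, matrix, config.ld_threshold)
    report["block"] = block.to_dict()

    # rate is taken over the whole analysis region (robust to degenerate blocks)
    ils = _stage("ils_test")(ils_mod.ils_test)(
        block,
        gmap,
        split_time=config.split_time,
        generation_time=config.generation_time,
        branch_factor=config.branch_factor,
        region=config.region,
    )
    sweep = _stage("ils_sensitivity")(ils_mod.split_time_sensitivity)(
        block,
        gmap,
        generation_time=config.generation_time,
        branch_factor=config.branch_factor,
        region=config.region,
    )
    report["ils"] = {
        **ils.to_dict(),
        "alpha": config.ils_alpha,
        "rejected": bool(ils.p_value < config.ils_alpha),
        "split_time_sensitivity": {f"{t:.0f}": p for t, p in sweep.items()},
    }

    defining_sites = [matrix.sites[matrix.site_index(s)] for s in config.defining]
    match = _stage("archaic_match")(archaic_mod.archaic_match)(
        block, archaic_table, defining_sites
    )
    report["archaic"] = match

    phylo_sites = _stage("select_phylo_sites")(archaic_mod.select_phylo_sites)(
        config.region, matrix, archaic_table, config.reference_archaic
    )
    chosen = _stage("choose_haplotypes")(_choose_haplotypes)(
        config, matrix, panel
    )
    alignment = _stage("build_alignment")(archaic_mod.build_alignment)(
        phylo_sites, matrix, chosen, archaic_table, seed=config.seed
    )
    tree = _stage("bootstrap_supports")(phylo_mod.bootstrap_supports)(
        alignment, B=config.bootstrap, seed=config.seed
    )
    rooted = _stage("root_tree")(phylo_mod.root_tree)(tree, "ancestral")
    carrier_taxon = f"{chosen[0][0]}_{chosen[0][1]}"
    clade = set(archaic_table.individuals) | {carrier_taxon}
    support = phylo_mod.clade_support(tree, clade)
    newick = gio.write_newick(rooted)
    report["phylogeny"] = {
        "n_selected_sites": len(phylo_sites),
        "n_alignment_sites": alignment.n_sites,
        "taxa": alignment.taxa,
        "carrier_taxon": carrier_taxon,
        "carrier_plus_archaic_support": support,
        "bootstrap_replicates": config.bootstrap,
        "seed": config.seed,
        "newick": newick.strip(),
    }

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        gio.write_report(report, out / "report.json")
        (out / "tree.nwk").write_text(newick)
        gio.write_block_bed(block, out / "block.bed")
        alignment.to_fasta(out / "alignment.fasta")
        _write_freq_tsv(out / "frequencies.tsv", freq)
    return report


def _choose_haplotypes(config: RunConfig, matrix, panel) -> list[tuple[str, int]]:
    """Default taxon choice: first carrier haplotype + first haplotype of the
    first n_outgroup samples of the outgroup population."""
    if config.carrier_haplotype:
        sample, side = config.carrier_haplotype.rsplit("/", 1)
        carrier = (sample, int(side))
    else:
        col = matrix.column(config.index)
        carrier = next(
            (hid for hid, allele in zip(matrix.haplotype_ids, col) if allele == 1), None
        )
        if carrier is None:
            raise ValueError("no haplotype carries the index variant")
    outgroup_samples = [s for s in matrix.samples if s in set(panel.samples_in(config.outgroup_pop))]
    if len(outgroup_samples) < config.n_outgroup:
        raise ValueError(
            f"only {len(outgroup_samples)} sample(s) of outgroup population "
            f"{config.outgroup_pop!r} in the matrix; {config.n_outgroup} requested"
        )
    return [carrier] + [(s, 1) for s in outgroup_samples[: config.n_outgroup]]


def _write_freq_tsv(path: Path, freq: dict[str, dict[str, float]]) -> None:
    groups = sorted({g for row in freq.values() for g in row})
    lines = ["variant\t" + "\t".join(groups)]
    for label, row in freq.items():
        lines.append(label + "\t" + "\t".join(f"{row.get(g, float('nan')):.4g}" for g in groups))
    path.write_text("\n".join(lines) + "\n")
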