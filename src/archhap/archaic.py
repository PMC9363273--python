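"""Comparison of a candidate haplotype with archaic genomes.

Given the block's defining variants and a table of archaic (Neandertal /
Denisovan) diploid calls, this module (1) summarizes each archaic
individual's genotypes and carrier status, (2) selects the sites used for
the phylogeny — modern segregating SNVs at which a chosen reference archaic
carries the variant homozygously — and (3) assembles a nucleotide alignment
of modern haplotypes, pseudo-haploidized archaic genomes and the ancestral
sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .genomic_io import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    GENOTYPE_LABELS,
    ArchaicGenotypeTable,
    HaplotypeMatrix,
    Region,
    VariantSite,
)
from .ld import HaplotypeBlock

logger = logging.getLogger("archhap")

GAP = "N"  # missing state in alignments

HOMOZYGOUS_CARRIER = "homozygous carrier"
HETEROZYGOUS_CARRIER = "heterozygous carrier"
PARTIAL_NON_CARRIER = "partial/non-carrier"
NO_DATA = "no data"


@dataclass
class AlignedHaplotypeSet:
    """A taxa × sites nucleotide alignment (A/C/G/T, ``N`` for missing).

    ``sites`` carries the per-column variant metadata; it may be ``None``
    for alignments loaded from bare FASTA.
    """

    taxa: list[str]
    sites: "list[VariantSite] | None"
    states: np.ndarray  # dtype '<U1', (n_taxa, n_sites)

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype="<U1")
        if self.states.ndim != 2 or self.states.shape[0] != len(self.taxa):
            raise ValueError("alignment shape does not match taxa")
        if self.sites is not None and self.states.shape[1] != len(self.sites):
            raise ValueError("alignment shape does not match sites")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        return int(self.states.shape[1])

    @classmethod
    def from_fasta(cls, path: "str | Path") -> "AlignedHaplotypeSet":
        taxa: list[str] = []
        seqs: list[str] = []
        current: list[str] = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line.startswith(">"):
                    if taxa:
                        seqs.append("".join(current))
                    taxa.append(line[1:].split()[0])
                    current = []
                elif line:
                    current.append(line.upper())
        if taxa:
            seqs.append("".join(current))
        if len({len(s) for s in seqs}) != 1:
            raise ValueError("FASTA sequences are not aligned (unequal lengths)")
        states = np.array([list(s) for s in seqs], dtype="<U1")
        return cls(taxa=taxa, sites=None, states=states)

    def sequence(self, taxon: str) -> str:
        return "".join(self.states[self.taxa.index(taxon)])

    def to_fasta(self, path: "str | Path | None" = None) -> str:
        out = []
        for i, t in enumerate(self.taxa):
            out.append(f">{t}\n{''.join(self.states[i])}\n")
        text = "".join(out)
        if path is not None:
            Path(path).write_text(text)
        return text


def archaic_match(
    block: HaplotypeBlock,
    table: ArchaicGenotypeTable,
    defining_sites: "list[VariantSite] | None" = None,
) -> dict[str, dict]:
    """Genotype summary and carrier verdict per archaic individual.

    The verdict over the defining sites is ``homozygous carrier`` when every
    called site is hom_alt, ``heterozygous carrier`` when at least one site
    is het and the rest are hom_alt, and ``partial/non-carrier`` otherwise
    (e.g. hom_ref at some sites but hom_alt at another, the Denisovan-like
    pattern).  Missing calls are reported but excluded from the verdict.
    """
    sites = defining_sites if defining_sites is not None else block.member_sites
    key_to_col = {s.key: j for j, s in enumerate(table.sites)}
    out: dict[str, dict] = {}
    for name in table.individuals:
        row = table.row(name)
        genotypes: dict[str, str] = {}
        calls: list[int] = []
        for site in sites:
            j = key_to_col.get(site.key)
            code = int(row[j]) if j is not None else MISSING
            genotypes[site.label] = GENOTYPE_LABELS[code]
            if code != MISSING:
                calls.append(code)
        if not calls:
            verdict = NO_DATA
        elif all(c == HOM_ALT for c in calls):
            verdict = HOMOZYGOUS_CARRIER
        elif all(c in (HET, HOM_ALT) for c in calls):
            verdict = HETEROZYGOUS_CARRIER
        else:
            verdict = PARTIAL_NON_CARRIER
        out[name] = {
            "genotypes": genotypes,
            "verdict": verdict,
            "n_missing": sum(g == "missing" for g in genotypes.values()),
        }
    return out


def select_phylo_sites(
    region: "str | Region",
    matrix: HaplotypeMatrix,
    table: ArchaicGenotypeTable,
    reference_archaic: str,
) -> list[VariantSite]:
    """Sites for the phylogeny: segregating modern SNVs, hom_alt in one archaic.

    Within ``region``, keep every matrix site that (a) segregates among the
    modern haplotypes (both alleles observed among non-missing entries) and
    (b) is a homozygous variant call in ``reference_archaic``.  Heterozygous
    or missing reference-archaic calls are excluded.  Deterministic,
    ascending position order.  Zero selected sites is an error — no
    phylogeny can be estimated.
    """
    region = Region.parse(region)
    ref_row = table.row(reference_archaic)
    key_to_col = {s.key: j for j, s in enumerate(table.sites)}
    selected: list[VariantSite] = []
    for j, site in enumerate(matrix.sites):
        if site.chrom != region.chrom or not (region.start <= site.pos <= region.end):
            continue
        col = matrix.data[:, j]
        called = col[col != MISSING]
        if called.size == 0 or called.min() == called.max():
            continue  # not segregating in the modern sample
        k = key_to_col.get(site.key)
        if k is None or ref_row[k] != HOM_ALT:
            continue
        selected.append(site)
    if not selected:
        raise ValueError(
            f"no usable sites in {region}: none segregate in the modern sample "
            f"and are homozygous-variant in {reference_archaic}"
        )
    return selected


def build_alignment(
    sites: list[VariantSite],
    matrix: HaplotypeMatrix,
    chosen_haplotypes: list[tuple[str, int]],
    table: ArchaicGenotypeTable,
    seed: int = 0,
    ancestral_label: str = "ancestral",
) -> AlignedHaplotypeSet:
    """Assemble the taxa × sites nucleotide alignment for tree building.

    Modern haplotypes are translated 0→ref, 1→alt; a missing or unphased
    allele in a chosen haplotype is an error.  Each archaic individual
    contributes one pseudo-haploid sequence: homozygous calls give that
    allele, heterozygous calls are resolved by a uniform draw seeded with
    ``seed`` (so an all-homozygous table is seed-independent), missing calls
    become ``N``.  The ancestral sequence comes from the sites' ancestral
    annotation; sites without a known ancestral allele are dropped with a
    warning, so the ancestral row is complete at every retained site.
    """
    kept = [s for s in sites if s.ancestral is not None]
    n_dropped = len(sites) - len(kept)
    if n_dropped:
        logger.warning("build_alignment: dropped %d site(s) lacking an ancestral allele",
                       n_dropped)
    if not kept:
        raise ValueError("no sites with known ancestral allele; alignment impossible")
    site_cols = [matrix.site_index(s) for s in kept]
    key_to_col = {s.key: j for j, s in enumerate(table.sites)}

    taxa: list[str] = []
    rows: list[list[str]] = []

    for sample, side in chosen_haplotypes:
        hap = matrix.haplotype_row(sample, side)
        seq = []
        for s, j in zip(kept, site_cols):
            allele = hap[j]
            if allele == MISSING:
                raise ValueError(f"haplotype {sample}/{side} is missing or unphased at {s.label}")
            seq.append(s.alt if allele == 1 else s.ref)
        taxa.append(f"{sample}_{side}")
        rows.append(seq)

    rng = np.random.default_rng(seed)
    for name in table.individuals:
        row = table.row(name)
        seq = []
        for s in kept:
            k = key_to_col.get(s.key)
            code = int(row[k]) if k is not None else MISSING
            if code == HOM_REF:
                seq.append(s.ref)
            elif code == HOM_ALT:
                seq.append(s.alt)
            elif code == HET:
                seq.append(s.alt if rng.integers(2) else s.ref)
            else:
                seq.append(GAP)
        taxa.append(name)
        rows.append(seq)

    taxa.append(ancestral_label)
    rows.append([s.ancestral for s in kept])

    return AlignedHaplotypeSet(taxa=taxa, sites=kept, states=np.array(rows, dtype="<U1"))
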