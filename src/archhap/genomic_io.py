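"""Readers, writers and the internal data model for the pipeline.

Everything downstream (LD, archaic matching, the ILS test, the phylogeny)
operates on the containers defined here: biallelic SNV sites, a phased
haplotype matrix, a population panel, a cumulative genetic map and a table
of archaic (Neandertal/Denisovan) genotype calls.

Coordinate conventions: 1-based inclusive everywhere internally (the VCF
convention); BED output converts to 0-based half-open.  Multi-allelic and
indel records are dropped on ingest — never split — and counted.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("archhap")

NUCLEOTIDES = frozenset("ACGT")

#: haplotype-matrix / genotype-table missing code
MISSING = -1

#: archaic genotype codes
HOM_REF, HET, HOM_ALT = 0, 1, 2
GENOTYPE_LABELS = {HOM_REF: "hom_ref", HET: "het", HOM_ALT: "hom_alt", MISSING: "missing"}


class PhasingError(ValueError):
    """Raised when a retained site carries an unphased heterozygous genotype."""


class EmptyRegionError(ValueError):
    """Raised when a query region contains no usable records."""


@dataclass(frozen=True)
class Region:
    """A 1-based inclusive genomic interval, e.g. ``chr10:96537863-96851277``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"malformed region {self.chrom}:{self.start}-{self.end}")

    @classmethod
    def parse(cls, text: "str | Region") -> "Region":
        if isinstance(text, Region):
            return text
        m = re.fullmatch(r"([\w.]+):([\d,]+)-([\d,]+)", text.strip())
        if m is None:
            raise ValueError(f"cannot parse region {text!r}; expected chrom:start-end")
        return cls(m.group(1), int(m.group(2).replace(",", "")), int(m.group(3).replace(",", "")))

    @property
    def length(self) -> int:
        """Span in bp, end − start (matches haplotype-length convention)."""
        return self.end - self.start

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass
class VariantSite:
    """A biallelic SNV.

    ``ancestral`` is the inferred ancestral (great-ape outgroup) allele and
    is filled in by :func:`read_ancestral`; ``None`` means unknown.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    rsid: str | None = None
    ancestral: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref not in NUCLEOTIDES or self.alt not in NUCLEOTIDES:
            raise ValueError(f"alleles must be single A/C/G/T bases: {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt identical at {self.chrom}:{self.pos}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def label(self) -> str:
        return self.rsid or f"{self.chrom}:{self.pos}_{self.ref}>{self.alt}"


@dataclass
class HaplotypeMatrix:
    """Phased alleles: one row per haplotype, one column per site.

    Entries are 0 (ref), 1 (alt) or :data:`MISSING`.  Row order is sample
    order with side 1 before side 2 for each sample.
    """

    sites: list[VariantSite]
    data: np.ndarray  # int8, (n_haplotypes, n_sites)
    haplotype_ids: list[tuple[str, int]]  # (sample, side in {1, 2})

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.int8)
        if self.data.ndim != 2 or self.data.shape != (len(self.haplotype_ids), len(self.sites)):
            raise ValueError("haplotype matrix shape does not match ids/sites")
        if len(self.haplotype_ids) % 2 != 0:
            raise ValueError("row count must be 2 x sample count")
        bad = ~np.isin(self.data, (0, 1, MISSING))
        if bad.any():
            raise ValueError("haplotype entries must be 0, 1 or missing")
        positions = [s.pos for s in self.sites]
        if any(b <= a for a, b in zip(positions, positions[1:])):
            raise ValueError("sites must be strictly increasing in position")

    @property
    def n_haplotypes(self) -> int:
        return self.data.shape[0]

    @property
    def n_sites(self) -> int:
        return self.data.shape[1]

    @property
    def samples(self) -> list[str]:
        return [s for s, side in self.haplotype_ids if side == 1]

    def site_index(self, site: "VariantSite | str | int") -> int:
        """Locate a site by object, rsid, position or ``chrom:pos`` string."""
        if isinstance(site, VariantSite):
            for i, s in enumerate(self.sites):
                if s.key == site.key:
                    return i
            raise KeyError(f"site {site.label} not in matrix")
        if isinstance(site, int):
            for i, s in enumerate(self.sites):
                if s.pos == site:
                    return i
            raise KeyError(f"no site at position {site}")
        for i, s in enumerate(self.sites):
            if s.rsid == site or f"{s.chrom}:{s.pos}" == site:
                return i
        raise KeyError(f"no site matching {site!r}")

    def column(self, site: "VariantSite | str | int") -> np.ndarray:
        return self.data[:, self.site_index(site)]

    def haplotype_row(self, sample: str, side: int) -> np.ndarray:
        try:
            i = self.haplotype_ids.index((sample, side))
        except ValueError:
            raise KeyError(f"haplotype {sample}/{side} not in matrix") from None
        return self.data[i]


@dataclass
class PopulationPanel:
    """sample → (population, super-population), 1000 Genomes style."""

    entries: dict[str, tuple[str, str]]

    def population(self, sample: str) -> str:
        return self._lookup(sample)[0]

    def super_population(self, sample: str) -> str:
        return self._lookup(sample)[1]

    def _lookup(self, sample: str) -> tuple[str, str]:
        try:
            return self.entries[sample]
        except KeyError:
            raise KeyError(f"sample {sample!r} missing from population panel") from None

    @property
    def super_populations(self) -> list[str]:
        return sorted({sp for _, sp in self.entries.values()})

    @property
    def populations(self) -> list[str]:
        return sorted({p for p, _ in self.entries.values()})

    def samples_in(self, group: str) -> list[str]:
        """Samples in a super-population, a population, or ``"ALL"``."""
        if group == "ALL":
            return list(self.entries)
        return [s for s, (p, sp) in self.entries.items() if group in (p, sp)]


@dataclass
class GeneticMap:
    """Cumulative genetic positions: strictly increasing bp, non-decreasing cM."""

    pos: np.ndarray  # bp
    cm: np.ndarray  # cumulative centimorgans

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=float)
        self.cm = np.asarray(self.cm, dtype=float)
        if self.pos.size != self.cm.size:
            raise ValueError("pos and cM arrays differ in length")
        if self.pos.size < 2:
            raise ValueError("a genetic map needs at least two points to define a rate")
        if not np.all(np.diff(self.pos) > 0):
            raise ValueError("map positions must be strictly increasing")
        if not np.all(np.diff(self.cm) >= 0):
            raise ValueError("cumulative cM must be non-decreasing")

    def cm_at(self, position: float) -> float:
        """Cumulative cM at a position, linearly interpolated; no extrapolation."""
        if position < self.pos[0] or position > self.pos[-1]:
            raise ValueError(
                f"position {position:.0f} outside map support "
                f"[{self.pos[0]:.0f}, {self.pos[-1]:.0f}]"
            )
        return float(np.interp(position, self.pos, self.cm))


@dataclass
class ArchaicGenotypeTable:
    """Diploid archaic calls at the modern site list.

    ``genotypes[i, j]`` is the call of individual *i* at site *j*:
    0 hom_ref, 1 het, 2 hom_alt, −1 missing (no call or unmatched record).
    """

    individuals: list[str]
    sites: list[VariantSite]
    genotypes: np.ndarray  # int8, (n_individuals, n_sites)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.individuals), len(self.sites)):
            raise ValueError("genotype table shape does not match individuals/sites")
        if not np.isin(self.genotypes, (MISSING, HOM_REF, HET, HOM_ALT)).all():
            raise ValueError("archaic genotypes must be coded -1/0/1/2")

    def individual_index(self, name: str) -> int:
        try:
            return self.individuals.index(name)
        except ValueError:
            raise KeyError(f"archaic individual {name!r} not in table") from None

    def row(self, name: str) -> np.ndarray:
        return self.genotypes[self.individual_index(name)]


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _is_biallelic_snv(ref: str, alts: Sequence[str]) -> bool:
    return (
        len(alts) == 1
        and len(ref) == 1
        and len(alts[0]) == 1
        and ref in NUCLEOTIDES
        and alts[0] in NUCLEOTIDES
    )


def read_phased_vcf(
    path: "str | Path", region: "str | Region"
) -> tuple[list[VariantSite], HaplotypeMatrix, dict[str, int]]:
    """Read phased diploid genotypes for a region from a VCF.

    Only biallelic SNVs are retained; multi-allelic and indel records are
    dropped and counted in the returned ``dropped`` dict.  Unphased
    heterozygous genotypes at a retained site are an error (phase of a
    homozygote is unambiguous and tolerated).

    Returns ``(sites, matrix, dropped)``.
    """
    from cyvcf2 import VCF

    region = Region.parse(region)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    sites: list[VariantSite] = []
    rows: list[np.ndarray] = []
    dropped = {"multiallelic": 0, "indel_or_non_snv": 0}
    n_records = 0
    for var in vcf:
        if var.CHROM != region.chrom or not (region.start <= var.POS <= region.end):
            continue
        n_records += 1
        if len(var.ALT) != 1:
            dropped["multiallelic"] += 1
            continue
        if not _is_biallelic_snv(var.REF, var.ALT):
            dropped["indel_or_non_snv"] += 1
            continue
        site = VariantSite(
            chrom=var.CHROM,
            pos=var.POS,
            ref=var.REF,
            alt=var.ALT[0],
            rsid=None if var.ID in (None, ".") else var.ID,
        )
        col = np.empty(2 * len(samples), dtype=np.int8)
        for k, gt in enumerate(var.genotypes):  # [allele1, allele2, phased]
            a, b, phased = gt[0], gt[1], gt[-1]
            if a >= 0 and b >= 0 and a != b and not phased:
                raise PhasingError(f"unphased heterozygous genotype for sample "
                                   f"{samples[k]} at {site.label}")
            col[2 * k] = a if a >= 0 else MISSING
            col[2 * k + 1] = b if b >= 0 else MISSING
        sites.append(site)
        rows.append(col)
    vcf.close()
    if n_records == 0:
        raise EmptyRegionError(f"no VCF records in region {region}")
    if not sites:
        raise EmptyRegionError(f"no biallelic SNVs in region {region}")
    hap_ids = [(s, side) for s in samples for side in (1, 2)]
    matrix = HaplotypeMatrix(sites=sites, data=np.column_stack(rows), haplotype_ids=hap_ids)
    n_drop = sum(dropped.values())
    if n_drop:
        logger.info("read_phased_vcf: dropped %d record(s): %s", n_drop, dropped)
    return sites, matrix, dropped


def read_genetic_map(path: "str | Path") -> GeneticMap:
    """Read a deCODE-style map TSV: position and cumulative cM columns.

    A header row is tolerated; columns named like ``pos``/``cM`` are used if
    present, otherwise the first two columns.  Non-monotone rows raise with
    the offending (1-based, header included) line number.
    """
    df = pd.read_csv(path, sep=r"\s+", comment="#")
    header_offset = 2  # data row i sits on file line i + 2 when a header is present
    if all(_is_number(c) for c in df.columns):
        # no header: re-read without one
        df = pd.read_csv(path, sep=r"\s+", comment="#", header=None)
        header_offset = 1
    pos_col = next((c for c in df.columns if str(c).lower() in ("pos", "position", "bp")), df.columns[0])
    cm_col = next((c for c in df.columns if str(c).lower() in ("cm", "ccm", "cum_cm", "cmorgan")), df.columns[1])
    pos = df[pos_col].to_numpy(dtype=float)
    cm = df[cm_col].to_numpy(dtype=float)
    if pos.size < 2:
        raise ValueError("genetic map has fewer than two rows; no interval rate is defined")
    dpos = np.diff(pos)
    if (dpos <= 0).any():
        i = int(np.argmax(dpos <= 0)) + 1
        raise ValueError(f"map positions not strictly increasing at line {i + header_offset}")
    dcm = np.diff(cm)
    if (dcm < 0).any():
        i = int(np.argmax(dcm < 0)) + 1
        raise ValueError(f"cumulative cM decreases at line {i + header_offset}")
    return GeneticMap(pos=pos, cm=cm)


def _is_number(x) -> bool:
    try:
        float(x)
        return True
    except (TypeError, ValueError):
        return False


def read_panel(path: "str | Path") -> PopulationPanel:
    """Read a 1000G-style panel TSV with sample/pop/super_pop columns."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    missing = [c for c in ("sample", "pop", "super_pop") if c not in cols]
    if missing:
        raise ValueError(f"panel file lacks column(s): {', '.join(missing)}")
    entries = {
        str(r[cols["sample"]]): (str(r[cols["pop"]]), str(r[cols["super_pop"]]))
        for _, r in df.iterrows()
    }
    return PopulationPanel(entries=entries)


def read_ancestral(path: "str | Path", sites: Sequence[VariantSite]) -> list[VariantSite]:
    """Annotate sites in place with ancestral alleles from a TSV or FASTA slice.

    TSV: two columns, position and allele (header tolerated).  FASTA: a
    single record whose header carries the slice coordinates as
    ``chrom:start-end`` or ``start=<pos>``; base *i* of the sequence is
    position start+i.  Lower-case alleles (low-confidence calls in Ensembl
    ancestral tracks) are uppercased; anything outside A/C/G/T is treated
    as unknown.  Returns the same site list for convenience.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.read(1)
    if first == ">":
        lookup = _ancestral_from_fasta(path)
    else:
        lookup = _ancestral_from_tsv(path)
    n = 0
    for site in sites:
        allele = lookup.get(site.pos)
        if allele is not None:
            allele = allele.upper()
        site.ancestral = allele if allele in NUCLEOTIDES else None
        n += site.ancestral is not None
    logger.info("read_ancestral: annotated %d/%d sites", n, len(sites))
    return list(sites)


def _ancestral_from_tsv(path: Path) -> dict[int, str]:
    lookup: dict[int, str] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) < 2 or not parts[0].lstrip("-").isdigit():
                continue  # header or malformed
            lookup[int(parts[0])] = parts[1]
    return lookup


def _ancestral_from_fasta(path: Path) -> dict[int, str]:
    with open(path) as fh:
        header = fh.readline().strip()
        seq = "".join(line.strip() for line in fh if not line.startswith(">"))
    m = re.search(r"start=(\d+)", header) or re.search(r":(\d+)-\d+", header)
    if m is None:
        raise ValueError("ancestral FASTA header must carry slice coordinates "
                         "(chrom:start-end or start=N)")
    start = int(m.group(1))
    return {start + i: base for i, base in enumerate(seq)}


def read_archaic(
    paths: "Iterable[str | Path] | str | Path", sites: Sequence[VariantSite]
) -> ArchaicGenotypeTable:
    """Read archaic genotype calls (VCF or TSV) matched to the modern sites.

    Records are matched on exact (chrom, pos, ref, alt); records with
    swapped ref/alt are excluded with a warning; unmatched sites stay
    missing.  TSV layout: columns chrom, pos, ref, alt, then one column per
    individual holding VCF-style diploid genotypes (``0/0``, ``0|1`` ...).
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    site_lookup = {s.key: j for j, s in enumerate(sites)}
    swapped_lookup = {(s.chrom, s.pos, s.alt, s.ref): j for j, s in enumerate(sites)}
    individuals: list[str] = []
    rows: list[np.ndarray] = []
    for path in paths:
        path = Path(path)
        if _looks_like_vcf(path):
            names, table = _archaic_from_vcf(path, site_lookup, swapped_lookup, len(sites))
        else:
            names, table = _archaic_from_tsv(path, site_lookup, swapped_lookup, len(sites))
        individuals.extend(names)
        rows.extend(table)
    return ArchaicGenotypeTable(
        individuals=individuals, sites=list(sites), genotypes=np.array(rows, dtype=np.int8)
    )


def _looks_like_vcf(path: Path) -> bool:
    with open(path) as fh:
        return fh.readline().startswith("##fileformat=VCF")


def _code_from_alleles(a: int, b: int) -> int:
    if a < 0 or b < 0:
        return MISSING
    return a + b  # 0/0→0, het→1, 1/1→2


def _archaic_from_vcf(path, site_lookup, swapped_lookup, n_sites):
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    names = list(vcf.samples)
    table = np.full((len(names), n_sites), MISSING, dtype=np.int8)
    for var in vcf:
        if len(var.ALT) != 1 or not _is_biallelic_snv(var.REF, var.ALT):
            continue
        key = (var.CHROM, var.POS, var.REF, var.ALT[0])
        if key not in site_lookup:
            if key in swapped_lookup:
                logger.warning("read_archaic: allele-swapped record at %s:%d excluded",
                               var.CHROM, var.POS)
            continue
        j = site_lookup[key]
        for i, gt in enumerate(var.genotypes):
            table[i, j] = _code_from_alleles(gt[0], gt[1])
    vcf.close()
    return names, list(table)


def _archaic_from_tsv(path, site_lookup, swapped_lookup, n_sites):
    df = pd.read_csv(path, sep="\t", dtype=str)
    fixed = ["chrom", "pos", "ref", "alt"]
    if list(df.columns[:4]) != fixed:
        raise ValueError("archaic TSV must start with columns chrom, pos, ref, alt")
    names = list(df.columns[4:])
    table = np.full((len(names), n_sites), MISSING, dtype=np.int8)
    for _, row in df.iterrows():
        key = (row["chrom"], int(row["pos"]), row["ref"], row["alt"])
        if key not in site_lookup:
            if key in swapped_lookup:
                logger.warning("read_archaic: allele-swapped record at %s:%s excluded",
                               row["chrom"], row["pos"])
            continue
        j = site_lookup[key]
        for i, name in enumerate(names):
            gt = str(row[name])
            alleles = re.split(r"[|/]", gt)
            if len(alleles) == 2 and all(a in ("0", "1") for a in alleles):
                table[i, j] = _code_from_alleles(int(alleles[0]), int(alleles[1]))
    return names, list(table)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_newick(tree, path: "str | Path | None" = None) -> str:
    """Serialize a tree (branch lengths + integer support labels) to Newick."""
    text = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    ).strip() + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def write_block_bed(block, path: "str | Path | None" = None) -> str:
    """One BED line (0-based half-open) for a haplotype block span."""
    line = f"{block.chrom}\t{block.span_start - 1}\t{block.span_end}\n"
    if path is not None:
        Path(path).write_text(line)
    return line


def write_report(results: Mapping, path: "str | Path | None" = None) -> str:
    """Serialize a (nested) result mapping to stable, human-diffable JSON."""
    text = json.dumps(results, indent=2, sort_keys=True, default=_jsonify) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "to_dict"):
        return obj.to_dict()
    raise TypeError(f"cannot serialize {type(obj)!r}")
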