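"""Linkage disequilibrium on phased haplotypes, and population allele frequencies.

r² is computed from phased haplotype counts (the co-segregation of alleles
on chromosomes), not from genotype correlation: with haplotype frequencies
p_AB, p_A, p_B,

    D  = p_AB − p_A · p_B
    r² = D² / (p_A (1−p_A) p_B (1−p_B))

Haplotypes missing at either site are excluded pairwise.  A site that is
monomorphic after that exclusion has no defined LD — this is an error
distinct from r² = 0.

The haplotype block around an index variant is the min–max envelope of all
sites whose r² with the index reaches the cutoff (no contiguity required),
and its length is span_end − span_start in bp.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genomic_io import (
    MISSING,
    HaplotypeMatrix,
    PopulationPanel,
    VariantSite,
)


class UndefinedLDError(ValueError):
    """LD is undefined: a site is monomorphic among the compared haplotypes."""


@dataclass
class HaplotypeBlock:
    """All sites linked (r² ≥ threshold) to an index variant, and their span."""

    index_site: VariantSite
    member_sites: list[VariantSite]
    threshold: float

    def __post_init__(self) -> None:
        if not any(s.key == self.index_site.key for s in self.member_sites):
            raise ValueError("index site must be a member of its own block")

    @property
    def chrom(self) -> str:
        return self.index_site.chrom

    @property
    def span_start(self) -> int:
        return min(s.pos for s in self.member_sites)

    @property
    def span_end(self) -> int:
        return max(s.pos for s in self.member_sites)

    @property
    def length(self) -> int:
        """Block length in bp, defined as span_end − span_start."""
        return self.span_end - self.span_start

    def to_dict(self) -> dict:
        return {
            "index": self.index_site.label,
            "chrom": self.chrom,
            "span_start": self.span_start,
            "span_end": self.span_end,
            "length": self.length,
            "threshold": self.threshold,
            "n_members": len(self.member_sites),
            "members": [s.label for s in self.member_sites],
        }


def r_squared(hap_a: np.ndarray, hap_b: np.ndarray) -> float:
    """Squared LD correlation between two haplotype columns.

    Both columns must come from the same haplotype matrix (aligned rows).
    Raises :class:`UndefinedLDError` if fewer than two complete haplotypes
    remain or either site is monomorphic among them.
    """
    hap_a = np.asarray(hap_a)
    hap_b = np.asarray(hap_b)
    if hap_a.shape != hap_b.shape:
        raise ValueError("haplotype columns differ in length")
    keep = (hap_a != MISSING) & (hap_b != MISSING)
    a = hap_a[keep].astype(float)
    b = hap_b[keep].astype(float)
    n = a.size
    if n < 2:
        raise UndefinedLDError(f"only {n} complete haplotype(s) at this site pair")
    p_a = a.mean()
    p_b = b.mean()
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        raise UndefinedLDError("monomorphic site after missing-data exclusion")
    p_ab = float(np.mean(a * b))
    d = p_ab - p_a * p_b
    # grouped so the expression is exactly symmetric in (a, b)
    var_a = p_a * (1.0 - p_a)
    var_b = p_b * (1.0 - p_b)
    r2 = d * d / (var_a * var_b)
    # clamp floating-point spill just outside [0, 1]
    return float(min(max(r2, 0.0), 1.0))


def allele_frequency(
    site: "VariantSite | str | int",
    matrix: HaplotypeMatrix,
    panel: PopulationPanel | None = None,
    group: str = "ALL",
) -> float:
    """Alternate-allele frequency of a site within a (super-)population.

    ``group`` is a super-population code, a population code, or ``"ALL"``.
    The count is over non-missing haplotypes of the group's samples.
    """
    col = matrix.column(site)
    if group == "ALL":
        keep = np.ones(matrix.n_haplotypes, dtype=bool)
    else:
        if panel is None:
            raise ValueError("a population panel is required for group frequencies")
        for sample in matrix.samples:
            panel._lookup(sample)  # every matrix sample must be on the panel
        members = set(panel.samples_in(group))
        keep = np.array([s in members for s, _ in matrix.haplotype_ids])
        if not keep.any():
            raise ValueError(f"no samples in group {group!r}")
    vals = col[keep]
    vals = vals[vals != MISSING]
    if vals.size == 0:
        raise ValueError(f"no called haplotypes for group {group!r} at this site")
    return float(np.mean(vals == 1))


def frequency_table(
    sites: "list[VariantSite | str]",
    matrix: HaplotypeMatrix,
    panel: PopulationPanel,
    groups: "list[str] | None" = None,
) -> dict[str, dict[str, float]]:
    """Per-site frequencies across super-populations (Table-1-shaped)."""
    groups = groups or panel.super_populations
    out: dict[str, dict[str, float]] = {}
    for site in sites:
        label = matrix.sites[matrix.site_index(site)].label
        out[label] = {g: allele_frequency(site, matrix, panel, g) for g in groups}
    return out


def ld_block(
    index: "VariantSite | str | int",
    matrix: HaplotypeMatrix,
    threshold: float = 0.8,
) -> HaplotypeBlock:
    """Delineate the haplotype block around an index variant.

    Members are all matrix sites with defined r² ≥ ``threshold`` against the
    index (the index itself included, r² = 1).  Sites with undefined LD
    (monomorphic, or no complete haplotype overlap) are skipped.  A
    monomorphic index is an error.
    """
    i = matrix.site_index(index)
    index_site = matrix.sites[i]
    col_i = matrix.data[:, i]
    called = col_i[col_i != MISSING]
    if called.size == 0 or len(set(called.tolist())) < 2:
        raise UndefinedLDError(f"index site {index_site.label} is monomorphic")
    members: list[VariantSite] = []
    for j, site in enumerate(matrix.sites):
        if j == i:
            members.append(site)
            continue
        try:
            r2 = r_squared(col_i, matrix.data[:, j])
        except UndefinedLDError:
            continue
        if r2 >= threshold:
            members.append(site)
    return HaplotypeBlock(index_site=index_site, member_sites=members, threshold=threshold)


def ld_matrix(
    sites: "list[VariantSite | str]", matrix: HaplotypeMatrix
) -> tuple[list[str], np.ndarray]:
    """Pairwise r² among a set of sites (labels, symmetric matrix)."""
    idx = [matrix.site_index(s) for s in sites]
    labels = [matrix.sites[i].label for i in idx]
    n = len(idx)
    out = np.ones((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            out[a, b] = out[b, a] = r_squared(matrix.data[:, idx[a]], matrix.data[:, idx[b]])
    return labels, out
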