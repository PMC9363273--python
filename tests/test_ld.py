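"""LD arithmetic, allele frequencies, and haplotype-block delineation."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from archhap import genomic_io as gio
from archhap.ld import (
    UndefinedLDError,
    allele_frequency,
    frequency_table,
    ld_block,
    ld_matrix,
    r_squared,
)
from archhap.synthetic_data import SimConfig, simulate_dataset


def brute_force_r2(a, b):
    """2x2 haplotype tabulation with exact rational arithmetic."""
    pairs = [(int(x), int(y)) for x, y in zip(a, b) if x >= 0 and y >= 0]
    n = len(pairs)
    n_ab = sum(1 for x, y in pairs if x == 1 and y == 1)
    p_a = Fraction(sum(x for x, _ in pairs), n)
    p_b = Fraction(sum(y for _, y in pairs), n)
    d = Fraction(n_ab, n) - p_a * p_b
    return float(d * d / (p_a * (1 - p_a) * p_b * (1 - p_b)))


def column_from_counts(n_ab, n_ab_, n_a_b, n_ab__):
    """Columns realizing joint haplotype counts (AB, Ab, aB, ab)."""
    a = [1] * (n_ab + n_ab_) + [0] * (n_a_b + n_ab__)
    b = [1] * n_ab + [0] * n_ab_ + [1] * n_a_b + [0] * n_ab__
    return np.array(a, dtype=np.int8), np.array(b, dtype=np.int8)


class TestRSquared:
    def test_identity(self):
        col = np.array([0, 1, 1, 0, 1], dtype=np.int8)
        assert r_squared(col, col) == 1.0

    def test_enumerated_counts(self):
        # joint counts n_AB=4, n_Ab=1, n_aB=1, n_ab=4 -> D=0.15, r2=0.36
        a, b = column_from_counts(4, 1, 1, 4)
        assert r_squared(a, b) == pytest.approx(0.36, abs=1e-12)

    def test_monomorphic_is_undefined_not_zero(self):
        a = np.array([1, 1, 1, 1], dtype=np.int8)
        b = np.array([0, 1, 0, 1], dtype=np.int8)
        with pytest.raises(UndefinedLDError):
            r_squared(a, b)

    def test_pairwise_missing_exclusion_can_make_site_monomorphic(self):
        a = np.array([1, 0, 0, 0], dtype=np.int8)
        b = np.array([-1, 1, 0, 1], dtype=np.int8)
        # dropping the row where b is missing leaves a monomorphic
        with pytest.raises(UndefinedLDError):
            r_squared(a, b)

    @given(st.integers(0, 2**31 - 1))
    def test_symmetry_and_relabel_invariance(self, seed):
        from tests.conftest import random_haplotype_columns

        rng = np.random.default_rng(seed)
        a, b = random_haplotype_columns(rng, int(rng.integers(4, 30)))
        r = r_squared(a, b)
        assert r == r_squared(b, a)
        assert r == pytest.approx(r_squared(1 - a, b), abs=1e-12)
        assert r == pytest.approx(r_squared(a, 1 - b), abs=1e-12)
        assert r == pytest.approx(brute_force_r2(a, b), abs=1e-12)


def _matrix_from_columns(cols, positions=None):
    cols = [np.asarray(c, dtype=np.int8) for c in cols]
    n_hap = len(cols[0])
    positions = positions or [100 * (i + 1) for i in range(len(cols))]
    sites = [gio.VariantSite("chr1", p, "A", "G", rsid=f"rs{i}")
             for i, p in enumerate(positions)]
    ids = [(f"S{k // 2}", k % 2 + 1) for k in range(n_hap)]
    return gio.HaplotypeMatrix(sites=sites, data=np.column_stack(cols), haplotype_ids=ids)


class TestAlleleFrequency:
    def test_hand_count(self):
        # 5 diploids, alt counts (0,1,1,1,0) -> 3/10
        col = np.array([0, 0, 1, 0, 0, 1, 1, 0, 0, 0], dtype=np.int8)
        matrix = _matrix_from_columns([col])
        panel = gio.PopulationPanel({f"S{i}": ("CEU", "EUR") for i in range(5)})
        assert allele_frequency("rs0", matrix, panel, "EUR") == pytest.approx(0.3)
        assert allele_frequency("rs0", matrix, group="ALL") == pytest.approx(0.3)

    def test_monomorphic_reference_is_zero(self):
        col = np.zeros(6, dtype=np.int8)
        matrix = _matrix_from_columns([col])
        assert allele_frequency("rs0", matrix) == 0.0

    def test_empty_group_errors(self):
        matrix = _matrix_from_columns([np.array([0, 1, 0, 1], dtype=np.int8)])
        panel = gio.PopulationPanel({"S0": ("CEU", "EUR"), "S1": ("CEU", "EUR")})
        with pytest.raises(ValueError, match="no samples"):
            allele_frequency("rs0", matrix, panel, "EAS")

    def test_sample_missing_from_panel_errors(self):
        matrix = _matrix_from_columns([np.array([0, 1, 0, 1], dtype=np.int8)])
        panel = gio.PopulationPanel({"S0": ("CEU", "EUR")})
        with pytest.raises(KeyError, match="S1"):
            allele_frequency("rs0", matrix, panel, "EUR")

    def test_perfectly_linked_sites_have_identical_group_frequencies(self):
        rng = np.random.default_rng(0)
        col = (rng.random(40) < 0.3).astype(np.int8)
        matrix = _matrix_from_columns([col, col.copy()])
        panel = gio.PopulationPanel(
            {f"S{i}": (("CEU", "EUR") if i < 10 else ("YRI", "AFR")) for i in range(20)}
        )
        table = frequency_table(["rs0", "rs1"], matrix, panel)
        assert table["rs0"] == table["rs1"]


class TestLdBlock:
    def test_singleton_block(self):
        rng = np.random.default_rng(3)
        cols = [(rng.random(30) < 0.5).astype(np.int8) for _ in range(4)]
        matrix = _matrix_from_columns(cols)
        block = ld_block("rs1", matrix, threshold=0.999)
        assert [s.rsid for s in block.member_sites] == ["rs1"]
        assert block.length == 0

    def test_monomorphic_index_errors(self):
        matrix = _matrix_from_columns([np.zeros(6, dtype=np.int8),
                                       np.array([0, 1, 0, 1, 0, 1], dtype=np.int8)])
        with pytest.raises(UndefinedLDError):
            ld_block("rs0", matrix)

    def test_site_order_permutation_invariance(self):
        rng = np.random.default_rng(11)
        base = (rng.random(40) < 0.4).astype(np.int8)
        cols = [base, (rng.random(40) < 0.5).astype(np.int8), base.copy(),
                (rng.random(40) < 0.5).astype(np.int8)]
        m1 = _matrix_from_columns(cols, positions=[100, 200, 300, 400])
        # permute site order (positions must stay ascending, so permute data)
        perm = [2, 0, 3, 1]
        m2 = _matrix_from_columns([cols[i] for i in perm],
                                  positions=[100, 200, 300, 400])
        b1 = ld_block("rs0", m1)
        idx2 = perm.index(0)
        b2 = ld_block(f"rs{idx2}", m2)
        assert len(b1.member_sites) == len(b2.member_sites)

    def test_planted_tract_recovered_to_within_one_flanking_site(self):
        ds = simulate_dataset(SimConfig(seed=6))
        truth = ds.truth
        block = ld_block(truth.index_rsid, ds.matrix)
        lo, hi = truth.tract
        assert lo <= block.span_start <= block.span_end <= hi
        # every segregating archaic-derived site inside the tract is a member,
        # so the block reaches the outermost detectable tract markers
        member_pos = {s.pos for s in block.member_sites}
        for pos, cls in truth.site_class.items():
            if cls == "archaic_derived" and lo <= pos <= hi:
                col = ds.matrix.column(pos)
                if 0 < col.sum() < len(col):
                    assert pos in member_pos

    def test_ld_matrix_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(8)
        cols = [(rng.random(30) < 0.5).astype(np.int8) for _ in range(3)]
        matrix = _matrix_from_columns(cols)
        labels, r2 = ld_matrix(["rs0", "rs1", "rs2"], matrix)
        assert labels == ["rs0", "rs1", "rs2"]
        np.testing.assert_allclose(r2, r2.T)
        np.testing.assert_allclose(np.diag(r2), 1.0)
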