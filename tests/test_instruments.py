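"""Instrument selection: p-value filter, LD clumping, F statistic, Steiger."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mrkit.errors import ConfigurationError, DomainError, ValidationError
from mrkit.instruments import (
    LDMatrix,
    f_statistic,
    filter_by_pvalue,
    ld_clump,
    snp_r2,
    steiger_filter,
)

from conftest import make_pairs, variant


class TestPvalueFilter:
    def test_threshold_splits_records(self):
        records = [variant(snp=f"rs{i}", p=p) for i, p in enumerate([1e-6, 2e-5, 1e-8])]
        kept = filter_by_pvalue(records, 1e-5)
        assert [r.pval for r in kept] == [1e-6, 1e-8]

    def test_vacuous_and_empty(self):
        records = [variant(snp=f"rs{i}", p=0.5) for i in range(3)]
        assert filter_by_pvalue(records, 1.0) == records
        assert filter_by_pvalue(records, 1e-5) == []


def _brute_force_clump(records, ld, r2_threshold, window_bp):
    """Independent re-enactment of greedy clumping, step by step."""
    remaining = sorted(records, key=lambda r: (r.pval, r.snp_id))
    index = []
    while remaining:
        head = remaining.pop(0)
        index.append(head)
        survivors = []
        for r in remaining:
            linked = (
                r.chrom == head.chrom
                and abs(r.pos - head.pos) <= window_bp
                and ld.r2_between(head.snp_id, r.snp_id) >= r2_threshold
            )
            if not linked:
                survivors.append(r)
        remaining = survivors
    return index


class TestLdClump:
    def test_linked_pair_keeps_smaller_p(self):
        a = variant(snp="rsA", pos=1_000_000, p=1e-8)
        b = variant(snp="rsB", pos=1_005_000, p=1e-6)
        ld = LDMatrix(("rsA", "rsB"), np.array([[1.0, 0.5], [0.5, 1.0]]))
        kept = ld_clump([a, b], ld, r2_threshold=0.001, window_kb=10_000)
        assert [r.snp_id for r in kept] == ["rsA"]

    def test_unlinked_snps_all_retained(self):
        records = [variant(snp=f"rs{i}", pos=(i + 1) * 10**6, p=10**-(i + 3)) for i in range(4)]
        ld = LDMatrix(tuple(r.snp_id for r in records), np.eye(4))
        kept = ld_clump(records, ld, 0.001, 10_000)
        assert {r.snp_id for r in kept} == {r.snp_id for r in records}

    def test_matches_brute_force_oracle(self, rng):
        n = 6
        records = [
            variant(snp=f"rs{i}", pos=1_000_000 + i * 2000, p=float(rng.uniform(1e-9, 1e-4)))
            for i in range(n)
        ]
        raw = rng.uniform(0, 1, (n, n))
        r2 = (raw + raw.T) / 2
        np.fill_diagonal(r2, 1.0)
        ld = LDMatrix(tuple(r.snp_id for r in records), r2)
        kept = ld_clump(records, ld, r2_threshold=0.3, window_kb=10_000)
        oracle = _brute_force_clump(records, ld, 0.3, 10_000 * 1000)
        assert [r.snp_id for r in kept] == [r.snp_id for r in oracle]

    def test_output_pairwise_independent(self, rng):
        n = 12
        records = [
            variant(snp=f"rs{i:02d}", pos=1_000_000 + i * 3000, p=float(rng.uniform(1e-9, 1e-4)))
            for i in range(n)
        ]
        raw = rng.uniform(0, 1, (n, n))
        r2 = (raw + raw.T) / 2
        np.fill_diagonal(r2, 1.0)
        ld = LDMatrix(tuple(r.snp_id for r in records), r2)
        kept = ld_clump(records, ld, r2_threshold=0.4, window_kb=10_000)
        for i, a in enumerate(kept):
            for b in kept[i + 1 :]:
                far = a.chrom != b.chrom or abs(a.pos - b.pos) > 10_000 * 1000
                assert far or ld.r2_between(a.snp_id, b.snp_id) < 0.4

    def test_unknown_snp_raises(self):
        ld = LDMatrix(("rsX",), np.array([[1.0]]))
        with pytest.raises(ConfigurationError, match="rs1"):
            ld_clump([variant(snp="rs1")], ld, 0.001, 10_000)


class TestLDMatrix:
    def test_validation(self):
        with pytest.raises(ValidationError):
            LDMatrix(("a", "b"), np.array([[1.0, 0.5], [0.4, 1.0]]))  # asymmetric
        with pytest.raises(ValidationError):
            LDMatrix(("a", "b"), np.array([[1.0, 0.5], [0.5, 0.9]]))  # diagonal
        with pytest.raises(ValidationError):
            LDMatrix(("a", "b"), np.array([[1.0, 1.5], [1.5, 1.0]]))  # range

    def test_tsv_round_trip(self, tmp_path):
        ld = LDMatrix(("rs1", "rs2"), np.array([[1.0, 0.25], [0.25, 1.0]]))
        path = tmp_path / "ld.tsv"
        ld.to_tsv(path)
        again = LDMatrix.from_tsv(path)
        assert again.snp_ids == ld.snp_ids
        np.testing.assert_allclose(again.r2, ld.r2)


class TestFStatistic:
    def test_zero_r2(self):
        s = f_statistic(0.0, 1000, 1)
        assert s.F == 0.0 and s.weak

    def test_hand_arithmetic(self):
        assert math.isclose(f_statistic(0.01, 1000, 1).F, 0.01 * 998 / 0.99, rel_tol=1e-12)
        assert not f_statistic(0.01, 1000, 1).weak
        assert math.isclose(f_statistic(0.02, 2000, 1).F, 0.02 * 1998 / 0.98, rel_tol=1e-12)

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            f_statistic(1.0, 1000, 1)
        with pytest.raises(DomainError):
            f_statistic(0.1, 2, 1)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(
        r2=st.floats(1e-6, 0.5),
        r2_step=st.floats(1e-6, 0.4),
        n=st.integers(10, 10**6),
        n_step=st.integers(1, 10**5),
        k=st.integers(1, 5),
    )
    def test_strictly_increasing_in_r2_and_n(self, r2, r2_step, n, n_step, k):
        base = f_statistic(r2, n, k).F
        assert f_statistic(r2 + r2_step, n, k).F > base
        assert f_statistic(r2, n + n_step, k).F > base


class TestSnpR2:
    def test_zero_beta(self):
        assert snp_r2(0.0, 0.01, 1000, eaf=0.3) == 0.0

    def test_eaf_formula(self):
        assert math.isclose(snp_r2(0.1, 0.01, 1000, eaf=0.5), 0.005, rel_tol=1e-12)

    def test_z_fallback(self):
        # z = 0.1/0.02 = 5 -> r2 = 25 / (25 + 998)
        assert math.isclose(snp_r2(0.1, 0.02, 1000), 25 / 1023, rel_tol=1e-12)

    def test_domain_error(self):
        with pytest.raises(DomainError):
            snp_r2(0.1, 0.01, 2)


class TestSteiger:
    def test_forced_ordering_retained(self):
        # exposure z = 6 vs outcome z = 1 at equal n: direction must hold
        pairs = make_pairs([0.06], [0.01], [0.01], [0.01], n_exp=5000, n_out=5000)
        retained, (rec,) = steiger_filter(pairs)
        assert rec.direction_ok and len(retained) == 1

    def test_tie_dropped_with_p_one(self):
        pairs = make_pairs([0.05], [0.01], [0.05], [0.01], n_exp=5000, n_out=5000)
        retained, (rec,) = steiger_filter(pairs)
        assert retained == [] and rec.p == 1.0

    def test_fisher_z_formula_oracle(self):
        # r2_exp = 0.01, r2_out = 0.001, n = 3000 on both sides
        n = 3000
        r2e, r2o = 0.01, 0.001
        bx, sy = 0.1, 0.1
        se = bx / math.sqrt(r2e / (1 - r2e) * (n - 2))  # invert the z-based r2
        so = sy / math.sqrt(r2o / (1 - r2o) * (n - 2)) * 1.0
        pairs = make_pairs([bx], [se], [sy], [so], n_exp=n, n_out=n)
        _, (rec,) = steiger_filter(pairs)
        assert math.isclose(rec.r2_exp, r2e, rel_tol=1e-9)
        assert math.isclose(rec.r2_out, r2o, rel_tol=1e-9)
        z = (math.atanh(math.sqrt(r2e)) - math.atanh(math.sqrt(r2o))) / math.sqrt(2 / (n - 3))
        expected_p = 2 * stats.norm.sf(abs(z))
        assert math.isclose(rec.p, expected_p, abs_tol=1e-10)

    def test_retained_set_invariant_to_order(self, rng):
        from conftest import draw_harmonized

        pairs = draw_harmonized(rng, 12, true_beta=0.1)
        fwd, _ = steiger_filter(pairs)
        rev, _ = steiger_filter(pairs[::-1])
        assert {h.snp_id for h in fwd} == {h.snp_id for h in rev}

    def test_small_n_rejected(self):
        pairs = make_pairs([0.1], [0.01], [0.0], [0.01], n_exp=3, n_out=5000)
        with pytest.raises(DomainError):
            steiger_filter(pairs)
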