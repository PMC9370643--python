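import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from canedet.det import (
    Call,
    ComparisonSpec,
    Exclusivity,
    ReplicateMode,
    adjust_bonferroni,
    call_dets,
    call_exclusive,
    compute_rpkm,
    fisher_exact_two_sided,
    log2_fold_change,
)
from canedet.errors import DomainError, SpecificationError
from canedet.io import canonical_design

from conftest import make_matrix


def fisher_oracle(ca, ta, cb, tb):
    """Exact-rational two-sided Fisher p by full enumeration.

    Integer hypergeometric weights C(ta, x) * C(tb, k - x); the two-sided p
    sums weights <= the observed one, with the same 1e-7 relative slack on
    the tie comparison expressed in exact integer arithmetic.
    """
    k = ca + cb
    lo, hi = max(0, k - tb), min(k, ta)
    weights = {x: math.comb(ta, x) * math.comb(tb, k - x) for x in range(lo, hi + 1)}
    w_obs = weights[ca]
    num = sum(w for w in weights.values() if w * 10**7 <= w_obs * (10**7 + 1))
    return Fraction(num, sum(weights.values()))


# ---------------------------------------------------------------------------
# RPKM


def test_rpkm_formula():
    assert compute_rpkm(0, 500, 1_000_000) == 0.0
    assert compute_rpkm(10, 500, 1_000_000) == pytest.approx(20.0)


def test_rpkm_exact_rational():
    expected = Fraction(7 * 10**9, 2_345_678 * 1405)
    assert compute_rpkm(7, 1405, 2_345_678) == pytest.approx(float(expected), rel=1e-14)


def test_rpkm_scale_invariance():
    for k in (1, 2, 10):
        assert compute_rpkm(3 * k, 700, 50_000 * k) == pytest.approx(
            compute_rpkm(3, 700, 50_000)
        )


def test_rpkm_sums_to_1e9_when_total_is_column_sum():
    rng = np.random.default_rng(5)
    counts = rng.integers(0, 100, size=30)
    lengths = rng.integers(200, 5000, size=30)
    total = counts.sum()
    rpkm = compute_rpkm(counts, lengths, total)
    assert float((rpkm * lengths).sum()) == pytest.approx(1e9, rel=1e-12)


def test_rpkm_domain_errors():
    with pytest.raises(DomainError):
        compute_rpkm(1, 0, 100)
    with pytest.raises(DomainError):
        compute_rpkm(1, 100, 0)


# ---------------------------------------------------------------------------
# log2 fold change


def test_log2fc_cases():
    assert log2_fold_change(20, 5) == pytest.approx(2.0)
    assert log2_fold_change(7.3, 7.3, pseudo=1.0) == 0.0
    assert log2_fold_change(0, 5, pseudo=0.25) == pytest.approx(math.log2(0.25 / 5.25))
    with pytest.raises(DomainError):
        log2_fold_change(0, 5, pseudo=0.0)


# ---------------------------------------------------------------------------
# Fisher exact


def test_fisher_examples():
    assert fisher_exact_two_sided(5, 100, 5, 100) == pytest.approx(1.0)
    assert fisher_exact_two_sided(0, 50, 0, 60) == pytest.approx(1.0)
    assert fisher_exact_two_sided(3, 4, 1, 4) == pytest.approx(34 / 70, abs=1e-12)


@settings(deadline=None, max_examples=200)
@given(
    ta=st.integers(1, 25),
    tb=st.integers(1, 25),
    data=st.data(),
)
def test_fisher_matches_exact_enumeration(ta, tb, data):
    ca = data.draw(st.integers(0, ta))
    cb = data.draw(st.integers(0, tb))
    p = fisher_exact_two_sided(ca, ta, cb, tb)
    assert p == pytest.approx(float(fisher_oracle(ca, ta, cb, tb)), abs=1e-12)


@settings(deadline=None, max_examples=100)
@given(
    ta=st.integers(1, 500),
    tb=st.integers(1, 500),
    data=st.data(),
)
def test_fisher_symmetry(ta, tb, data):
    ca = data.draw(st.integers(0, ta))
    cb = data.draw(st.integers(0, tb))
    assert fisher_exact_two_sided(ca, ta, cb, tb) == pytest.approx(
        fisher_exact_two_sided(cb, tb, ca, ta), rel=1e-10
    )


def test_fisher_preconditions():
    with pytest.raises(DomainError):
        fisher_exact_two_sided(5, 4, 0, 4)
    with pytest.raises(DomainError):
        fisher_exact_two_sided(0, 0, 0, 4)


# ---------------------------------------------------------------------------
# Bonferroni


def test_bonferroni_cases():
    assert adjust_bonferroni([0.01], m=1).tolist() == [0.01]
    assert adjust_bonferroni([0.01] * 10).tolist() == pytest.approx([0.1] * 10)
    assert adjust_bonferroni([0.2] * 10).tolist() == [1.0] * 10


@settings(deadline=None, max_examples=100)
@given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
def test_bonferroni_monotone_cap(ps):
    adj = adjust_bonferroni(ps)
    assert (adj >= np.asarray(ps)).all()
    assert (adj <= 1.0).all()


def test_bonferroni_bad_m():
    with pytest.raises(DomainError):
        adjust_bonferroni([0.1, 0.2], m=1)


# ---------------------------------------------------------------------------
# DET calling


def test_self_comparison_yields_no_calls():
    counts = np.tile([[50], [3], [200]], (1, 2))  # identical libraries
    m = make_matrix(counts, totals=[10_000, 10_000])
    spec = ComparisonSpec("self", ("L0",), ("L1",))
    table = call_dets(m, spec)
    assert len(table.called) == 0


def test_three_transcript_toy():
    m = make_matrix([[100, 1], [1, 100], [10, 10]], totals=[10_000, 10_000])
    spec = ComparisonSpec("toy", ("L0",), ("L1",))
    table = call_dets(m, spec)
    assert table.m_tests == 3
    calls = table.frame["call"]
    assert calls["T00000"] == Call.UP_A.value
    assert calls["T00001"] == Call.UP_B.value
    assert calls["T00002"] == Call.NS.value
    # Bonferroni-adjusted p agrees with the exact enumeration oracle, m = 3
    for t, (ca, cb) in zip(["T00000", "T00001", "T00002"], [(100, 1), (1, 100), (10, 10)]):
        expect = min(1.0, 3 * float(fisher_oracle(ca, 10_000, cb, 10_000)))
        assert table.frame.loc[t, "p_adj"] == pytest.approx(expect, rel=1e-9)


def test_det_record_invariants(simulated, genotype_spec):
    matrix, _, _ = simulated
    table = call_dets(matrix, genotype_spec)
    f = table.frame
    assert ((f["p_raw"] >= 0) & (f["p_raw"] <= f["p_adj"]) & (f["p_adj"] <= 1)).all()
    called = f[f["call"] != Call.NS.value]
    assert (called["p_adj"] < table.alpha).all()
    up_a = f[f["call"] == Call.UP_A.value]
    assert (up_a["rpkm_a"] > up_a["rpkm_b"]).all()


def test_consensus_drops_contradictory_replicate():
    # replicate L1 of group A contradicts L0; pooled still favors A
    counts = [[400, 2, 5, 5]]
    m = make_matrix(counts, totals=[10_000] * 4)
    spec_pooled = ComparisonSpec("p", ("L0", "L1"), ("L2", "L3"))
    spec_cons = ComparisonSpec(
        "c", ("L0", "L1"), ("L2", "L3"), replicate_mode=ReplicateMode.PER_PAIR_CONSENSUS
    )
    pooled = call_dets(m, spec_pooled)
    consensus = call_dets(m, spec_cons)
    assert pooled.frame.iloc[0]["call"] == Call.UP_A.value
    assert consensus.frame.iloc[0]["call"] == Call.NS.value


def test_unknown_library_in_spec(simulated):
    matrix, _, _ = simulated
    spec = ComparisonSpec("bad", ("nope",), ("SP_ST_R1",))
    with pytest.raises(SpecificationError, match="nope"):
        call_dets(matrix, spec)


# ---------------------------------------------------------------------------
# exclusivity rule


def _exclusive_matrix(row):
    """One transcript across the canonical 16 libraries (8 high then 8 low)."""
    design = canonical_design()
    libs = [d.library_id for d in design]
    return make_matrix([row], totals=[1000] * 16, libraries=libs), design


def test_exclusive_low_five_of_eight():
    row = [0] * 8 + [1, 1, 1, 1, 1, 0, 0, 0]
    m, design = _exclusive_matrix(row)
    result = call_exclusive(m, design)
    assert result == {"T00000": Exclusivity.EXCLUSIVE_B}


def test_not_exclusive_below_threshold():
    row = [0] * 8 + [1, 1, 1, 1, 0, 0, 0, 0]
    m, design = _exclusive_matrix(row)
    assert call_exclusive(m, design) == {}


def test_not_exclusive_with_leak():
    row = [1] + [0] * 7 + [1, 1, 1, 1, 1, 1, 0, 0]
    m, design = _exclusive_matrix(row)
    assert call_exclusive(m, design) == {}


def test_exclusive_threshold_validation():
    m, design = _exclusive_matrix([0] * 16)
    with pytest.raises(SpecificationError):
        call_exclusive(m, design, min_positive_libraries=9)
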