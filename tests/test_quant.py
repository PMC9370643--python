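import math

import numpy as np
import pytest

from canedet.errors import DomainError, EmptyInputError, FormatError
from canedet.quant import (
    CtRecord,
    DilutionSeries,
    MpnStatus,
    cfu_per_gram,
    concordance,
    expression_ratio,
    mpn_estimate,
    mpn_log_likelihood,
    read_ct_table,
    read_dilution_series,
    relative_expression,
)
from canedet.simulate import simulate_dilution_series


def ct(target, ref1, ref2):
    return CtRecord(sample_id="s", target_ct=target, reference_cts=(ref1, ref2))


# ---------------------------------------------------------------------------
# delta-Ct expression


@pytest.mark.parametrize(
    "target, refs, expected",
    [(25, (25, 25), 1.0), (24, (25, 25), 2.0), (27, (24, 26), 0.25)],
)
def test_relative_expression(target, refs, expected):
    assert relative_expression(ct(target, *refs)) == pytest.approx(expected)


def test_relative_expression_doubles_per_cycle():
    base = relative_expression(ct(30, 25, 25))
    assert relative_expression(ct(29, 25, 25)) == pytest.approx(2 * base)
    assert relative_expression(ct(31, 25, 25)) == pytest.approx(base / 2)


def test_ct_validation():
    with pytest.raises(FormatError):
        CtRecord(sample_id="s", target_ct=25.0, reference_cts=(25.0,))
    with pytest.raises(FormatError):
        ct(float("nan"), 25, 25)
    with pytest.raises(DomainError):
        relative_expression(ct(25, 25, 25), efficiency=1.0)


def test_expression_ratio_cases():
    r = expression_ratio([4, 4], [1, 1])
    assert r.ratio == pytest.approx(4.0)
    assert r.log2_ratio == pytest.approx(2.0)
    assert r.sd == 0.0
    same = expression_ratio([2.5, 2.5, 2.5], [2.5, 2.5])
    assert same.ratio == pytest.approx(1.0) and same.log2_ratio == pytest.approx(0.0)
    with pytest.raises(DomainError):
        expression_ratio([1.0], [0.0])
    with pytest.raises(EmptyInputError):
        expression_ratio([], [1.0])


def test_expression_ratio_propagated_sd():
    rng = np.random.default_rng(11)
    a = rng.normal(8.0, 0.5, size=6)
    b = rng.normal(2.0, 0.2, size=6)
    r = expression_ratio(a, b)
    expected = (a.mean() / b.mean()) * math.sqrt(
        (a.std(ddof=1) / a.mean()) ** 2 + (b.std(ddof=1) / b.mean()) ** 2
    )
    assert r.sd == pytest.approx(expected)


# ---------------------------------------------------------------------------
# concordance with RNA-seq


def test_concordance_examples():
    qpcr = {"a": 1.0, "b": -2.0, "c": 0.5, "d": 1.0}
    rnaseq = {"a": 2.0, "b": -1.0, "c": -0.5, "d": 3.0}
    summary = concordance(qpcr, rnaseq)
    assert summary.fraction_agreeing == pytest.approx(0.75)
    assert summary.n_shared == 4
    full = concordance({"a": 1.0}, {"a": 0.2})
    assert full.fraction_agreeing == 1.0
    with pytest.raises(EmptyInputError):
        concordance({"x": 1.0}, {"y": 1.0})


def test_concordance_zero_matches_nothing():
    summary = concordance({"a": 0.0}, {"a": 1.0})
    assert summary.fraction_agreeing == 0.0


def test_concordance_random_signs_near_half():
    rng = np.random.default_rng(2)
    n = 1000
    qpcr = {f"t{i}": float(rng.choice([-1.0, 1.0])) for i in range(n)}
    rnaseq = {f"t{i}": float(rng.choice([-1.0, 1.0])) for i in range(n)}
    frac = concordance(qpcr, rnaseq).fraction_agreeing
    assert abs(frac - 0.5) < 3 * math.sqrt(0.25 / n)


# ---------------------------------------------------------------------------
# MPN


def test_mpn_all_negative():
    series = DilutionSeries((-1, -2, -3), 3, (0, 0, 0))
    est = mpn_estimate(series)
    assert est.mpn_per_ml == 0.0
    assert est.status is MpnStatus.ALL_NEGATIVE
    assert cfu_per_gram(est, series) == 0.0


def test_mpn_all_positive_lower_bound():
    series = DilutionSeries((-1, -2), 3, (3, 3))
    est = mpn_estimate(series)
    assert est.status is MpnStatus.ALL_POSITIVE
    assert est.mpn_per_ml >= 1e14


def test_mpn_single_dilution_closed_form():
    # 2 of 3 tubes positive at delivered volume 0.01 mL
    series = DilutionSeries((-1,), 3, (2,), inoculum_volume=0.1)
    est = mpn_estimate(series)
    assert est.mpn_per_ml == pytest.approx(-math.log(1 - 2 / 3) / 0.01, rel=1e-9)


def test_mpn_matches_grid_oracle():
    series = DilutionSeries((-1, -2, -3), 3, (3, 1, 0))
    est = mpn_estimate(series)
    grid = np.logspace(-2, 6, 100_000)
    c_grid = grid[np.argmax(mpn_log_likelihood(grid, series))]
    assert est.mpn_per_ml == pytest.approx(c_grid, rel=5e-3)


def test_mpn_monotone_in_positives():
    base = DilutionSeries((-1, -2, -3), 5, (4, 2, 0))
    more = DilutionSeries((-1, -2, -3), 5, (4, 3, 0))
    assert mpn_estimate(more).mpn_per_ml > mpn_estimate(base).mpn_per_ml


def test_mpn_ci_brackets_estimate():
    series = DilutionSeries((-1, -2, -3), 3, (3, 1, 0))
    est = mpn_estimate(series, with_ci=True)
    lo, hi = est.log10_ci
    assert lo < math.log10(est.mpn_per_ml) < hi


def test_mpn_per_g_conversion():
    series = DilutionSeries((-1, -2, -3), 3, (3, 1, 0), homogenate_factor=10.0)
    est = mpn_estimate(series)
    assert est.mpn_per_g == pytest.approx(est.mpn_per_ml * 10.0)
    scaled = DilutionSeries((-1, -2, -3), 3, (3, 1, 0), homogenate_factor=9.9)
    est2 = mpn_estimate(scaled)
    assert cfu_per_gram(est2, scaled) == pytest.approx(est2.mpn_per_ml * 9.9)


def test_dilution_series_validation():
    with pytest.raises(FormatError):
        DilutionSeries((-1, -2), 3, (4, 0))
    with pytest.raises(FormatError):
        DilutionSeries((-1, -2), 3, (1,))


def test_mpn_estimate_improves_with_more_tubes():
    true_conc = 500.0
    spec3 = DilutionSeries(tuple(range(-1, -6, -1)), 3, (0,) * 5)
    spec24 = DilutionSeries(tuple(range(-1, -6, -1)), 24, (0,) * 5)
    errors = {3: [], 24: []}
    for tubes, spec in ((3, spec3), (24, spec24)):
        for seed in range(60):
            observed = simulate_dilution_series(true_conc, spec, seed=seed)
            est = mpn_estimate(observed)
            if est.status is MpnStatus.OK:
                errors[tubes].append(abs(est.mpn_per_ml - true_conc) / true_conc)
    assert np.median(errors[24]) < np.median(errors[3])


# ---------------------------------------------------------------------------
# file I/O


def test_read_ct_table(tmp_path):
    (tmp_path / "ct.tsv").write_text(
        "sample_id\treplicate\ttarget_ct\tref1_ct\tref2_ct\nSP\t1\t24.0\t25.0\t25.0\n"
    )
    [rec] = read_ct_table(tmp_path / "ct.tsv")
    assert relative_expression(rec) == pytest.approx(2.0)


def test_read_dilution_series(tmp_path):
    (tmp_path / "d.tsv").write_text(
        "exponent\ttubes\tpositives\n-1\t3\t3\n-2\t3\t1\n-3\t3\t0\n"
    )
    series = read_dilution_series(tmp_path / "d.tsv")
    assert series.positives == (3, 1, 0)
    assert mpn_estimate(series).status is MpnStatus.OK
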