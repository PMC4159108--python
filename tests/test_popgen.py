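import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mirpopgen import popgen
from mirpopgen.model import MISSING

from conftest import make_variant_table


# ---------------------------------------------------------------------------
# allele frequencies
# ---------------------------------------------------------------------------

def test_frequency_all_hom_ref(tiny_panel):
    table = make_variant_table([("chr1", 100, "A", "G", True)], tiny_panel)
    freqs = popgen.allele_frequencies(table, tiny_panel, "population")
    assert (freqs.freq.to_numpy() == 0).all()


def test_frequency_one_het_of_five(tiny_panel):
    # population AF1 has 3 diploids; build a 5-diploid group via region Africa
    n = tiny_panel.n_samples
    gt = np.zeros((1, n), dtype=np.int8)
    gt[0, 0] = 1
    table = make_variant_table([("chr1", 100, "A", "G", True)], tiny_panel, gt)
    freqs = popgen.allele_frequencies(table, tiny_panel, "population")
    key = table.variants[0].key
    assert freqs.freq.loc["AF1", key] == pytest.approx(1 / 6)
    assert freqs.n_chrom.loc["AF1", key] == 6


def test_frequency_with_missing_excluded(tiny_panel):
    # one 0/1 among 4 called of 5 -> 1/8
    idx = tiny_panel.sample_indices(region="Africa")[:5]
    n = tiny_panel.n_samples
    gt = np.zeros((1, n), dtype=np.int8)
    gt[0, :] = MISSING
    gt[0, idx] = 0
    gt[0, idx[0]] = 1
    gt[0, idx[4]] = MISSING
    table = make_variant_table([("chr1", 100, "A", "G", True)], tiny_panel, gt)
    freqs = popgen.allele_frequencies(table, tiny_panel, "region")
    key = table.variants[0].key
    assert freqs.freq.loc["Africa", key] == pytest.approx(0.125)
    assert freqs.n_chrom.loc["Africa", key] == 8


def test_frequency_zero_called_is_missing(tiny_panel):
    n = tiny_panel.n_samples
    gt = np.full((1, n), MISSING, dtype=np.int8)
    table = make_variant_table([("chr1", 100, "A", "G", True)], tiny_panel, gt)
    freqs = popgen.allele_frequencies(table, tiny_panel, "population")
    assert np.isnan(freqs.freq.to_numpy()).all()


# ---------------------------------------------------------------------------
# Watterson's theta
# ---------------------------------------------------------------------------

def test_watterson_examples():
    assert popgen.watterson_theta(0, 10, 1000).theta_per_site == 0.0
    est = popgen.watterson_theta(11, 4, 1000)
    assert est.a_n == pytest.approx(1 + 1 / 2 + 1 / 3)
    assert est.theta_per_site == pytest.approx(0.006)
    # harmonic base case: n=2 -> a_1 = 1 -> theta = S/L
    assert popgen.watterson_theta(5, 2, 100).theta_per_site == pytest.approx(0.05)


def test_watterson_errors():
    with pytest.raises(ValueError):
        popgen.watterson_theta(1, 1, 100)
    with pytest.raises(ValueError):
        popgen.watterson_theta(1, 4, 0)
    with pytest.raises(ValueError):
        popgen.watterson_theta(-1, 4, 100)


@given(
    S=st.integers(min_value=0, max_value=10_000),
    n=st.integers(min_value=2, max_value=500),
    L=st.integers(min_value=1, max_value=10**6),
)
def test_watterson_halves_when_length_doubles(S, n, L):
    t1 = popgen.watterson_theta(S, n, L).theta_per_site
    t2 = popgen.watterson_theta(S, n, 2 * L).theta_per_site
    assert t2 == pytest.approx(t1 / 2)


# ---------------------------------------------------------------------------
# Weir–Cockerham
# ---------------------------------------------------------------------------

def wc_oracle(p1, n1, p2, n2):
    """Independent route: haploid ANOVA mean squares.

    MSP = sum n_i (p_i - pbar)^2 / (r-1); MSG = sum n_i p_i (1-p_i) / sum (n_i - 1);
    a = (MSP - MSG)/n_c; w = MSG; theta = (MSP - MSG) / (MSP + (n_c - 1) MSG).
    """
    r = 2
    p_bar = (n1 * p1 + n2 * p2) / (n1 + n2)
    msp = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / (r - 1)
    msg = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / ((n1 - 1) + (n2 - 1))
    n_c = (n1 + n2 - (n1**2 + n2**2) / (n1 + n2)) / (r - 1)
    a = (msp - msg) / n_c
    denom = msp + (n_c - 1) * msg
    if denom == 0 and msp == msg:
        return a, msg, None
    return a, msg, (msp - msg) / denom


def test_wc_examples():
    assert popgen.wc_fst(1.0, 10, 0.0, 10).theta_hat == pytest.approx(1.0)
    c = popgen.wc_fst(0.5, 10, 0.5, 10)
    assert c.theta_hat == pytest.approx(-1 / 9)
    assert c.theta_reported == 0.0
    c = popgen.wc_fst(0.8, 10, 0.2, 10)
    assert c.a == pytest.approx(0.1622, abs=1e-4)
    assert c.w == pytest.approx(0.1778, abs=1e-4)
    assert c.theta_hat == pytest.approx(0.477, abs=1e-3)


def test_wc_undefined_monomorphic():
    c = popgen.wc_fst(0.0, 10, 0.0, 20)
    assert not c.defined
    assert math.isnan(c.theta_hat)
    c = popgen.wc_fst(1.0, 10, 1.0, 20)
    assert not c.defined


def test_wc_input_validation():
    with pytest.raises(ValueError):
        popgen.wc_fst(0.5, 1, 0.5, 10)
    with pytest.raises(ValueError):
        popgen.wc_fst(1.5, 10, 0.5, 10)


def test_wc_matches_anova_oracle():
    rng = np.random.default_rng(1234)
    for _ in range(10_000):
        n1 = int(rng.integers(2, 200))
        n2 = int(rng.integers(2, 200))
        p1 = float(rng.integers(0, n1 + 1)) / n1
        p2 = float(rng.integers(0, n2 + 1)) / n2
        comp = popgen.wc_fst(p1, n1, p2, n2)
        a, w, theta = wc_oracle(p1, n1, p2, n2)
        assert comp.a == pytest.approx(a, abs=1e-12)
        assert comp.w == pytest.approx(w, abs=1e-12)
        if theta is None:
            assert not comp.defined
        else:
            assert comp.theta_hat == pytest.approx(theta, abs=1e-12)


@settings(max_examples=300, deadline=None)
@given(
    p1=st.floats(min_value=0, max_value=1),
    p2=st.floats(min_value=0, max_value=1),
    n1=st.integers(min_value=2, max_value=500),
    n2=st.integers(min_value=2, max_value=500),
)
def test_wc_symmetry(p1, p2, n1, n2):
    ab = popgen.wc_fst(p1, n1, p2, n2)
    ba = popgen.wc_fst(p2, n2, p1, n1)
    assert ab.a == pytest.approx(ba.a, rel=1e-12, abs=1e-15)
    assert ab.w == pytest.approx(ba.w, rel=1e-12, abs=1e-15)
    if ab.defined:
        assert ab.theta_hat == pytest.approx(ba.theta_hat, rel=1e-12, abs=1e-15)


def test_wc_theta_bounded_above_by_one():
    rng = np.random.default_rng(5)
    for _ in range(2000):
        n1, n2 = int(rng.integers(2, 50)), int(rng.integers(2, 50))
        c = popgen.wc_fst(float(rng.random()), n1, float(rng.random()), n2)
        if c.defined:
            assert c.theta_hat <= 1 + 1e-12
            assert 0 <= c.theta_reported <= 1


# ---------------------------------------------------------------------------
# Welch test
# ---------------------------------------------------------------------------

def test_welch_identical_groups():
    res = popgen.welch_test([0, 0.5, 1], [0, 0.5, 1])
    assert res.t == 0 and res.p == 1


def test_welch_example_vs_hand_values():
    a = np.array([0, 1, 1, 2]) / 2
    b = np.array([2, 2, 1, 2]) / 2
    res = popgen.welch_test(a, b)
    assert res.t == pytest.approx(-1.567, abs=1e-3)
    assert res.df == pytest.approx(4.97, abs=1e-2)


def test_welch_matches_scipy_reference():
    rng = np.random.default_rng(7)
    for _ in range(500):
        a = rng.integers(0, 3, size=rng.integers(2, 40)) / 2
        b = rng.integers(0, 3, size=rng.integers(2, 40)) / 2
        if a.var() == 0 and b.var() == 0:
            continue
        res = popgen.welch_test(a, b)
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert res.t == pytest.approx(ref.statistic, rel=1e-10)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-10)


def test_welch_degenerate_cases():
    res = popgen.welch_test([0.5, 0.5], [1.0, 1.0])
    assert res.degenerate and res.p == 0
    with pytest.raises(ValueError):
        popgen.welch_test([0.5], [0.5, 1.0])


# ---------------------------------------------------------------------------
# percentile threshold
# ---------------------------------------------------------------------------

def test_percentile_constant():
    assert popgen.percentile_threshold([0.3] * 50, 0.95) == pytest.approx(0.3)


def test_percentile_linear_interpolation():
    values = np.arange(100) / 100  # 0.00 .. 0.99
    assert popgen.percentile_threshold(values, 0.95) == pytest.approx(0.9405)


def test_percentile_errors():
    with pytest.raises(ValueError):
        popgen.percentile_threshold([], 0.95)
    with pytest.raises(ValueError):
        popgen.percentile_threshold([0.1], 1.0)
    with pytest.raises(ValueError):
        popgen.percentile_threshold([0.1, float("nan")], 0.5)


# ---------------------------------------------------------------------------
# PD classification
# ---------------------------------------------------------------------------

def _rec(key, theta, p_welch):
    return popgen.FstRecord(
        key, "Africa-pool|nonAfrica-pool", "pooled", 0.5, 0.1, 20, 20,
        0.1, 0.1, theta, max(theta, 0.0), True, 1.0, 10.0, p_welch,
    )


def test_classify_pd_rules():
    q95, q99 = 0.2, 0.4
    recs = [
        _rec("v1", 0.2, 0.01),   # exactly at q95, significant -> PD
        _rec("v2", 0.45, 0.2),   # above q99 but p too large -> none
        _rec("v3", 0.1, 0.001),  # below q95 -> none
        _rec("v4", 0.4, 0.04),   # at q99 -> HPD
    ]
    labels = {c.variant_key: c.label for c in popgen.classify_pd(recs, q95, q99)}
    assert labels == {"v1": "PD", "v2": "none", "v3": "none", "v4": "HPD"}


def test_hpd_implies_pd_threshold_ordering():
    recs = [_rec("v", 0.5, 0.01)]
    (c,) = popgen.classify_pd(recs, 0.2, 0.4)
    assert c.label == "HPD"
    assert c.theta >= c.q99 >= c.q95


# ---------------------------------------------------------------------------
# PSMA
# ---------------------------------------------------------------------------

def test_detect_psma(tiny_panel):
    n = tiny_panel.n_samples
    af1 = tiny_panel.sample_indices(population="AF1")
    eu1 = tiny_panel.sample_indices(population="EU1")
    gt = np.zeros((3, n), dtype=np.int8)
    gt[0, af1[0]] = 1                      # private to AF1, freq 1/6
    gt[1, af1[0]] = 1
    gt[1, eu1[0]] = 1                      # in two populations -> not PSMA
    gt[2, af1] = [2, 2, 1]                 # private to AF1, freq 5/6 -> high
    specs = [
        ("chr1", 100, "A", "G", True),
        ("chr1", 200, "C", "T", True),
        ("chr1", 300, "G", "A", True),
    ]
    table = make_variant_table(specs, tiny_panel, gt)
    records, density = popgen.detect_psma(table, tiny_panel)
    assert len(records) == 2
    assert all(r.population == "AF1" for r in records)
    high = {r.variant_key: r.high_frequency for r in records}
    assert high[table.variants[0].key] is False
    assert high[table.variants[2].key] is True
    assert density["AF1"] == pytest.approx(2 / 3)  # 2 PSMAs / 3 genomes
    assert density["EU1"] == 0.0


def test_psma_high_frequency_at_threshold(tiny_panel):
    n = tiny_panel.n_samples
    af1 = tiny_panel.sample_indices(population="AF1")
    gt = np.zeros((1, n), dtype=np.int8)
    gt[0, af1] = [2, 1, 0]  # freq 0.5 exactly
    table = make_variant_table([("chr1", 100, "A", "G", True)], tiny_panel, gt)
    records, _ = popgen.detect_psma(table, tiny_panel)
    assert records[0].high_frequency  # >= 0.5 is inclusive


# ---------------------------------------------------------------------------
# fst_scan contrasts
# ---------------------------------------------------------------------------

def test_contrast_enumeration(cohort_panel):
    contrasts = popgen.build_contrasts(cohort_panel)
    by_kind = {}
    for c in contrasts:
        by_kind.setdefault(c.kind, []).append(c)
    assert len(by_kind["population"]) == 91  # C(14,2)
    assert len(by_kind["region"]) == 6       # C(4,2) incl. Admixed
    assert len(by_kind["pooled"]) == 1
    pooled = by_kind["pooled"][0]
    assert len(pooled.idx_a) == 32 and len(pooled.idx_b) == 25


def test_fst_scan_minimal(tiny_panel):
    n = tiny_panel.n_samples
    gt = np.zeros((1, n), dtype=np.int8)
    gt[0, tiny_panel.sample_indices(population="AF1")] = 2
    table = make_variant_table([("chr1", 100, "A", "G", True)], tiny_panel, gt)
    contrasts = [
        c for c in popgen.build_contrasts(tiny_panel)
        if c.kind == "population" and {c.group_a, c.group_b} == {"AF1", "EU1"}
    ]
    records = popgen.fst_scan(table, tiny_panel, contrasts)
    assert len(records) == 1
    assert records[0].theta_hat == pytest.approx(1.0)


def test_fst_scan_pooled_excludes_admixed(tiny_panel):
    n = tiny_panel.n_samples
    gt = np.zeros((1, n), dtype=np.int8)
    adm = tiny_panel.sample_indices(population="ADM")
    gt[0, adm] = 2  # alt only in the admixed population
    table = make_variant_table([("chr1", 100, "A", "G", True)], tiny_panel, gt)
    records = popgen.fst_scan(
        table, tiny_panel,
        [c for c in popgen.build_contrasts(tiny_panel) if c.kind == "pooled"],
    )
    (rec,) = records
    assert rec.n1 == 2 * 6 and rec.n2 == 2 * 6  # 2 African + 2 non-African pops
    assert rec.p1 == 0 and rec.p2 == 0
    assert not rec.defined  # monomorphic once admixed carriers are excluded


def test_fst_scan_empty_group_is_error(tiny_panel):
    table = make_variant_table([("chr1", 100, "A", "G", True)], tiny_panel)
    bad = popgen.Contrast("population", "X", "Y", np.array([], dtype=int),
                          np.array([0]))
    with pytest.raises(ValueError, match="empty"):
        popgen.fst_scan(table, tiny_panel, [bad])


def test_fst_scan_deduplicates_overlapping_hairpin_records(tiny_panel):
    import numpy as np

    n = tiny_panel.n_samples
    gt = np.zeros((2, n), dtype=np.int8)
    gt[:, 0] = 1
    specs = [("chr1", 100, "A", "G", True)] * 2  # same variant twice
    table = make_variant_table(specs, tiny_panel, gt)
    records = popgen.fst_scan(
        table, tiny_panel,
        [c for c in popgen.build_contrasts(tiny_panel) if c.kind == "pooled"],
    )
    assert len(records) == 1
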