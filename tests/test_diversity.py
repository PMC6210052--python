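import math
import warnings
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ithfish.classify import SYSTEMS, classify_cells
from ithfish.diversity import (
    DegenerateSplitWarning,
    ClonalShiftResult,
    InfiniteDivergenceError,
    SampleComposition,
    composition,
    kl_divergence,
    kl_divergence_vectors,
    mean_shannon_by_group,
    median_split,
    shannon_index,
)

from conftest import make_cells


def comp(fracs, system="phenotype4", pid="P0", tp="pre", n=100):
    return SampleComposition(pid, tp, system, np.asarray(fracs, float), n)


# ---------------------------------------------------------------------------
# independent literal-summation oracles


def shannon_oracle(fracs) -> float:
    total = 0.0
    for f in fracs:
        if f > 0:
            total -= f * math.log2(f)
    return total


def kl_oracle(p, q, epsilon=0.0) -> float:
    """Literal term-by-term evaluation with exact Fraction smoothing arithmetic."""
    p = [Fraction(x).limit_denominator(10**12) for x in p]
    q = [Fraction(x).limit_denominator(10**12) for x in q]
    eps = Fraction(epsilon).limit_denominator(10**12)
    if eps > 0 and any(x == 0 for x in p):
        p = [x + eps for x in p]
    if eps > 0 and any(x == 0 for x in q):
        q = [x + eps for x in q]
    sp, sq = sum(p), sum(q)
    total = 0.0
    for pi, qi in zip(p, q):
        pi, qi = pi / sp, qi / sq
        if pi > 0:
            total += float(pi) * math.log2(float(pi / qi))
    return total


# ---------------------------------------------------------------------------
# Shannon index


@pytest.mark.parametrize(
    "fracs, expected",
    [
        ((0.25, 0.25, 0.25, 0.25), 2.0),
        ((1.0, 0.0, 0.0), 0.0),
        ((0.5, 0.25, 0.25), 1.5),
    ],
)
def test_shannon_known_values(fracs, expected):
    system = "phenotype4" if len(fracs) == 4 else "genotype3"
    assert shannon_index(comp(fracs, system)) == pytest.approx(expected, abs=1e-12)


@settings(deadline=None, derandomize=True, max_examples=200)
@given(st.lists(st.floats(0.0, 1.0), min_size=2, max_size=12).filter(lambda v: sum(v) > 0))
def test_shannon_bounds(raw):
    f = np.array(raw) / sum(raw)
    si = shannon_index(f)
    assert -1e-12 <= si <= math.log2(len(f)) + 1e-12


def test_shannon_maximal_at_uniform():
    assert shannon_index(np.full(12, 1 / 12)) == pytest.approx(math.log2(12), abs=1e-12)


# ---------------------------------------------------------------------------
# Kullback-Leibler


def test_kl_identical_is_zero():
    p = comp((0.3, 0.3, 0.4), "genotype3")
    res = kl_divergence(p, comp((0.3, 0.3, 0.4), "genotype3", tp="post"))
    assert res.kl_bits == 0.0
    assert np.allclose(res.deltas, 0)


def test_kl_half_vs_quarter_exact():
    expected = 0.5 * math.log2(0.5 / 0.25) + 0.5 * math.log2(0.5 / 0.75)
    got = kl_divergence_vectors([0.5, 0.5], [0.25, 0.75], epsilon=0)
    assert got == pytest.approx(expected, abs=1e-15)
    assert got == pytest.approx(0.20751874963942185, abs=1e-12)


def test_kl_with_smoothing_matches_high_precision_oracle():
    p, q, eps = [1.0, 0.0], [0.5, 0.5], 1e-6
    got = kl_divergence_vectors(p, q, epsilon=eps)
    assert math.isfinite(got)
    assert got == pytest.approx(kl_oracle(p, q, eps), abs=1e-12)


def test_kl_zero_mass_without_smoothing_raises():
    with pytest.raises(InfiniteDivergenceError, match="epsilon"):
        kl_divergence_vectors([0.5, 0.5], [1.0, 0.0], epsilon=0)


def test_kl_nonnegative_and_asymmetric():
    p, q = np.array([0.7, 0.2, 0.1]), np.array([0.2, 0.5, 0.3])
    assert kl_divergence_vectors(p, q, 0) > 0
    assert kl_divergence_vectors(p, q, 0) != kl_divergence_vectors(q, p, 0)


@settings(deadline=None, derandomize=True, max_examples=200)
@given(
    st.lists(st.floats(0.01, 1.0), min_size=3, max_size=3),
    st.lists(st.floats(0.01, 1.0), min_size=3, max_size=3),
)
def test_kl_gibbs_inequality(pr, qr):
    p = np.array(pr) / sum(pr)
    q = np.array(qr) / sum(qr)
    kl = kl_divergence_vectors(p, q, epsilon=1e-6)
    assert kl >= -1e-9
    if np.allclose(p, q, atol=1e-12):
        assert kl <= 1e-9


def test_kl_vectorized_agrees_with_literal_summation():
    rng = np.random.default_rng(42)
    worst = 0.0
    for _ in range(1000):
        m = rng.integers(2, 13)
        p = rng.dirichlet(np.ones(m))
        q = rng.dirichlet(np.ones(m))
        worst = max(worst, abs(kl_divergence_vectors(p, q, 0) - kl_oracle(p, q)))
        worst = max(worst, abs(shannon_index(p) - shannon_oracle(p)))
    assert worst <= 1e-12


def test_kl_requires_matching_system():
    with pytest.raises(ValueError, match="system"):
        kl_divergence(comp((1, 0, 0), "genotype3"), comp((1, 0, 0, 0), "phenotype4", tp="post"))


# ---------------------------------------------------------------------------
# compositions


def test_composition_all_one_class():
    cells = classify_cells(make_cells([{"her2_area_px": 400.0}] * 10))
    c = composition(cells, "genotype3")
    assert c.fractions.tolist() == [0.0, 0.0, 1.0]
    assert c.n_cells == 10


def test_composition_phenotype_fractions():
    cells = classify_cells(
        make_cells(
            [{"er_intensity": 100.0, "her2_intensity": 400.0}] * 2
            + [{"er_intensity": 10.0, "her2_intensity": 400.0}] * 2
        )
    )
    c = composition(cells, "phenotype4")
    assert c.fractions.tolist() == [0.5, 0.5, 0.0, 0.0]


def test_composition_rejects_mixed_samples():
    cells = classify_cells(make_cells([{"patient_id": "A"}, {"patient_id": "B"}]))
    with pytest.raises(ValueError, match="single"):
        composition(cells, "phenotype4")


def test_composition_empty_input():
    with pytest.raises(ValueError):
        composition(classify_cells(make_cells([])), "phenotype4")


def test_planted_fractions_recovered_at_large_n():
    rng = np.random.default_rng(0)
    planted = np.array([0.6, 0.3, 0.1])
    labels = rng.choice(["norm", "gain", "amp"], size=10_000, p=planted)
    cells = make_cells([{} for _ in range(10_000)])
    cells["phenotype"] = "HER2-/ER-"
    cells["genotype"] = labels
    cells["combined"] = cells["phenotype"] + " " + cells["genotype"]
    c = composition(cells, "genotype3")
    assert np.abs(c.fractions - planted).max() <= 0.03


# ---------------------------------------------------------------------------
# mean SI and median split


def test_mean_shannon_by_group():
    si = pd.Series([0.5, 1.5, 0.8], index=["a", "b", "c"])
    groups = pd.Series(["g1", "g1", "g2"], index=["a", "b", "c"])
    out = mean_shannon_by_group(si, groups)
    assert out["g1"] == pytest.approx(1.0)
    assert out["g2"] == pytest.approx(0.8)


def shift(pid, kl):
    return ClonalShiftResult(pid, "genotype3", kl, np.zeros(3))


def test_median_split_two_by_two():
    out = median_split([shift("a", 0.1), shift("b", 0.2), shift("c", 0.8), shift("d", 0.9)])
    groups = {s.patient_id: s.group for s in out}
    assert groups == {"a": "KL_low", "b": "KL_low", "c": "KL_high", "d": "KL_high"}


def test_median_split_twenty_distinct_is_ten_ten():
    out = median_split([shift(f"p{i}", 0.05 * (i + 1)) for i in range(20)])
    assert sum(s.group == "KL_high" for s in out) == 10
    assert sum(s.group == "KL_low" for s in out) == 10


def test_median_split_all_identical_warns_degenerate():
    with pytest.warns(DegenerateSplitWarning):
        out = median_split([shift("a", 0.3), shift("b", 0.3), shift("c", 0.3)])
    assert all(s.group == "KL_low" for s in out)


def test_median_split_tie_at_median_goes_low():
    out = median_split([shift("a", 0.1), shift("b", 0.2), shift("c", 0.9)])
    assert {s.patient_id: s.group for s in out} == {"a": "KL_low", "b": "KL_low", "c": "KL_high"}


def test_median_split_needs_two_patients():
    with pytest.raises(ValueError):
        median_split([shift("a", 0.1)])
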