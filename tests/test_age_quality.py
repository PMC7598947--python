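import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hdss import (
    AgeQualityReport,
    SimulationConfig,
    age_quality_report,
    classify,
    generate,
    myers,
    tabulate,
    un_joint_score,
    whipple,
)
from hdss.core import AgeSexTabulation


def brute_force_whipple(counts, digits, lo, hi):
    total = heaped = 0.0
    for age in range(lo, hi + 1):
        c = counts[age] if age < len(counts) else 0.0
        total += c
        if age % 10 in digits:
            heaped += c
    return 100.0 * heaped / (len(digits) / 10.0 * total)


def brute_force_myers(counts, lo=10, hi=89):
    """Independent loop-coded Myers: equal-decade blended sums, half the
    deviation total."""
    ndec = (hi - lo + 1) // 10
    blended = []
    for d in range(10):
        s1 = sum(counts[lo + 10 * k + d] for k in range(ndec - 1))
        s2 = sum(counts[lo + 10 * (k + 1) + d] for k in range(ndec - 1))
        blended.append((d + 1) * s1 + (9 - d) * s2)
    total = sum(blended)
    return sum(abs(100.0 * b / total - 10.0) for b in blended) / 2.0


class TestWhipple:
    def test_uniform_no_preference(self):
        assert whipple(np.ones(100)) == pytest.approx(100.0)

    def test_total_heaping_limit(self):
        z = np.zeros(100)
        z[::5] = 1
        assert whipple(z) == pytest.approx(500.0)

    def test_single_digit_baseline_is_100(self):
        u = np.ones(100)
        assert whipple(u, digits=(5,)) == pytest.approx(100.0)
        assert whipple(u, digits=(0,)) == pytest.approx(100.0)

    def test_matches_brute_force_on_heaped_census(self):
        b = generate(SimulationConfig(seed=9, n_households=800, heaping_prob=0.5))
        sy = tabulate(b.census).single_year_total
        for digits in [(0, 5), (0,), (5,)]:
            assert whipple(sy, digits=digits) == pytest.approx(
                brute_force_whipple(sy, digits, 23, 62)
            )

    def test_empty_range_rejected(self):
        with pytest.raises(ValueError):
            whipple(np.ones(100), age_range=(60, 40))


class TestMyers:
    def test_uniform_is_exactly_zero(self):
        assert myers(np.ones(100)) == pytest.approx(0.0, abs=1e-12)

    def test_total_concentration_is_90(self):
        z = np.zeros(100)
        z[::10] = 1
        assert myers(z) == pytest.approx(90.0)

    def test_matches_independent_implementation(self):
        b = generate(SimulationConfig(seed=9, n_households=800, heaping_prob=0.5))
        sy = tabulate(b.census).single_year_total
        assert myers(sy) == pytest.approx(brute_force_myers(sy))

    def test_blended_percentages_conserve(self):
        """Deviation of 0 for uniform implies blended shares sum to 100; check
        an irregular distribution still conserves the percentage total."""
        rng = np.random.default_rng(0)
        counts = rng.integers(50, 150, 100).astype(float)
        # reconstruct the blended shares the same way the index does
        ndec = 8
        blended = np.empty(10)
        for d in range(10):
            first = counts[[10 + 10 * k + d for k in range(ndec - 1)]].sum()
            last = counts[[20 + 10 * k + d for k in range(ndec - 1)]].sum()
            blended[d] = (d + 1) * first + (9 - d) * last
        pct = 100 * blended / blended.sum()
        assert pct.sum() == pytest.approx(100.0)

    def test_insufficient_span_rejected(self):
        with pytest.raises(ValueError):
            myers(np.ones(100), age_range=(10, 24))

    @settings(max_examples=30, deadline=None)
    @given(st.integers(min_value=2, max_value=1000))
    def test_scale_invariance(self, k):
        rng = np.random.default_rng(1)
        counts = rng.integers(1, 100, 100).astype(float)
        assert myers(counts * k) == pytest.approx(myers(counts))
        assert whipple(counts * k) == pytest.approx(whipple(counts))


class TestUNJointScore:
    def test_pencil_and_paper_toy_table(self):
        tab = AgeSexTabulation(
            band_edges=np.array([0, 5, 10, 15]),
            counts_male=np.array([100, 110, 90, 100]),
            counts_female=np.array([100, 100, 100, 100]),
            single_year_male=np.zeros(20, dtype=int),
            single_year_female=np.zeros(20, dtype=int),
        )
        # sex ratios 100,110,90,100 -> mean |diff| = 40/3; male age ratios
        # 110/95 and 90/105 (x100), female exactly 100
        expected = 3 * (40 / 3) + ((100 * 110 / 95 - 100) + (100 - 100 * 90 / 105)) / 2
        assert un_joint_score(tab, max_age=20) == pytest.approx(expected)

    def test_smooth_expected_population_scores_accurate(self):
        """Expected (noise-free) counts from the generator's stable age
        distribution with equal sexes score below the 'accurate' cutoff."""
        cfg = SimulationConfig()
        dist = cfg.age_distribution() * 1e6
        edges = np.arange(0, 90, 5)
        band = np.array([dist[lo:lo + 5].sum() for lo in edges])
        tab = AgeSexTabulation(edges, band / 2, band / 2,
                               np.zeros(100), np.zeros(100))
        assert un_joint_score(tab) < 20

    def test_alternating_distortion_scores_worse(self):
        cfg = SimulationConfig()
        dist = cfg.age_distribution() * 1e6
        edges = np.arange(0, 90, 5)
        band = np.array([dist[lo:lo + 5].sum() for lo in edges])
        smooth = AgeSexTabulation(edges, band / 2, band / 2,
                                  np.zeros(100), np.zeros(100))
        m = band / 2 * np.where(np.arange(len(band)) % 2, 2.0, 1.0)
        rough = AgeSexTabulation(edges, m, band / 2, np.zeros(100), np.zeros(100))
        assert un_joint_score(rough) > un_joint_score(smooth)

    def test_zero_female_band_rejected(self):
        tab = AgeSexTabulation(
            np.array([0, 5, 10, 15]),
            np.array([10, 10, 10, 10]),
            np.array([10, 0, 10, 10]),
            np.zeros(20), np.zeros(20),
        )
        with pytest.raises(ValueError):
            un_joint_score(tab, max_age=20)


class TestClassify:
    @pytest.mark.parametrize(
        "w,label",
        [(274, "very rough"), (323, "very rough"), (100, "highly accurate"),
         (107, "fairly accurate"), (120, "approximate"), (150, "rough")],
    )
    def test_whipple_categories(self, w, label):
        rep = AgeQualityReport(whipple_combined=w, whipple_digit={}, myers=0)
        assert classify(rep)["whipple"] == label

    @pytest.mark.parametrize("s,label", [(10, "accurate"), (30, "inaccurate"),
                                         (110, "highly inaccurate")])
    def test_joint_score_categories(self, s, label):
        rep = AgeQualityReport(whipple_combined=100, whipple_digit={}, myers=0,
                               un_joint_score=s)
        assert classify(rep)["un_joint_score"] == label


def test_full_report_on_heaped_census(bundle):
    rep = age_quality_report(tabulate(bundle.census))
    assert rep.whipple_combined > 175  # heaping_prob 0.5 -> very rough
    assert 0 <= rep.myers <= 90
    assert classify(rep)["whipple"] == "very rough"
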