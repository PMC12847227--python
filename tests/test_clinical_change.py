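import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from likertnorm.clinical_change import (
    DEFAULT_BANDS,
    ChangeThresholds,
    OutcomeCategory,
    SeverityBands,
    classify_change,
    compute_thresholds,
    cs_cutoff,
    rci,
    severity_band,
    standard_error_measurement,
)
from likertnorm.scoring import DescriptiveStats


class TestStandardError:
    def test_perfect_reliability(self):
        assert standard_error_measurement(8.0, 1.0) == 0.0

    def test_published_t_scale_inputs(self):
        assert standard_error_measurement(8.86, 0.88) == pytest.approx(3.069, abs=5e-4)

    def test_zero_sd(self):
        assert standard_error_measurement(0.0, 0.5) == 0.0

    def test_reliability_bounds(self):
        with pytest.raises(ValueError):
            standard_error_measurement(5.0, 1.2)


class TestRCI:
    def test_zero_se(self):
        for lv in (80, 90, 95):
            assert rci(0.0, lv) == 0.0

    def test_published_95(self):
        se = standard_error_measurement(8.86, 0.88)
        assert round(rci(se, 95), 1) == 8.5

    def test_level_ordering(self):
        se = 3.0
        assert rci(se, 80) < rci(se, 90) < rci(se, 95)

    def test_unsupported_level(self):
        with pytest.raises(ValueError):
            rci(1.0, 99)

    @given(st.floats(0, 100), st.floats(1, 10))
    @settings(max_examples=50, deadline=None)
    def test_homogeneous_degree_one(self, se, c):
        assert rci(c * se, 95) == pytest.approx(c * rci(se, 95), rel=1e-12)


class TestCSCutoff:
    def test_published_raw_scale(self):
        clin = DescriptiveStats(n=9983, mean=51.14, sd=14.20)
        norm = DescriptiveStats(n=11789, mean=61.72, sd=8.76)
        assert round(cs_cutoff(clin, norm), 2) == 57.68

    def test_published_t_scale(self):
        clin = DescriptiveStats(n=9983, mean=37.98, sd=15.69)
        norm = DescriptiveStats(n=11789, mean=50.06, sd=8.86)
        assert round(cs_cutoff(clin, norm), 1) == 45.7

    def test_equal_means(self):
        clin = DescriptiveStats(n=10, mean=50.0, sd=14.0)
        norm = DescriptiveStats(n=10, mean=50.0, sd=9.0)
        assert cs_cutoff(clin, norm) == 50.0

    @given(
        m1=st.floats(10, 80), m2=st.floats(10, 80),
        s1=st.floats(0.5, 20), s2=st.floats(0.5, 20),
    )
    @settings(max_examples=60, deadline=None)
    def test_strictly_between_means(self, m1, m2, s1, s2):
        clin = DescriptiveStats(n=10, mean=m1, sd=s1)
        norm = DescriptiveStats(n=10, mean=m2, sd=s2)
        c = cs_cutoff(clin, norm)
        lo, hi = sorted((m1, m2))
        if m1 != m2:
            assert lo < c < hi


def _thresholds(rci95=8.5, cs=45.7, higher=True):
    se = rci95 / (1.960 * np.sqrt(2))
    return ChangeThresholds(
        se=se,
        rci={80: rci(se, 80), 90: rci(se, 90), 95: rci(se, 95)},
        cs=cs,
        higher_is_better=higher,
    )


class TestClassifyChange:
    def test_recovered(self):
        assert classify_change(40, 50, _thresholds()) is OutcomeCategory.RECOVERED

    def test_unchanged_when_equal(self):
        assert classify_change(50, 50, _thresholds()) is OutcomeCategory.UNCHANGED

    def test_relapsed(self):
        assert classify_change(50, 41, _thresholds()) is OutcomeCategory.RELAPSED

    def test_improved_but_not_recovered(self):
        # starts functional, so reliable improvement is not "Recovered"
        assert classify_change(50, 60, _thresholds()) is OutcomeCategory.RELIABLY_IMPROVED

    def test_deteriorated_without_crossing(self):
        # starts already dysfunctional
        assert (
            classify_change(40, 30, _thresholds())
            is OutcomeCategory.RELIABLY_DETERIORATED
        )

    def test_truth_table_exhaustive_exclusive(self):
        """Every (pre, post) cell on a grid spanning all threshold/crossing
        combinations yields exactly one category, and the category implied by
        first principles."""
        thr = _thresholds()
        grid = np.arange(30.0, 62.0, 1.7)
        for pre, post in itertools.product(grid, grid):
            got = classify_change(pre, post, thr, level=95)
            delta = post - pre
            r = thr.rci[95]
            pre_fn, post_fn = pre >= thr.cs, post >= thr.cs
            if delta >= r:
                want = (
                    OutcomeCategory.RECOVERED
                    if (not pre_fn and post_fn)
                    else OutcomeCategory.RELIABLY_IMPROVED
                )
            elif delta <= -r:
                want = (
                    OutcomeCategory.RELAPSED
                    if (pre_fn and not post_fn)
                    else OutcomeCategory.RELIABLY_DETERIORATED
                )
            else:
                want = OutcomeCategory.UNCHANGED
            assert got is want, (pre, post)

    @given(st.floats(20, 80), st.floats(20, 80))
    @settings(max_examples=100, deadline=None)
    def test_direction_reversal_flips(self, pre, post):
        up = classify_change(pre, post, _thresholds(higher=True))
        # negating scores and the cutoff under the reversed direction must
        # give the identical category
        thr_down = _thresholds(cs=-45.7, higher=False)
        down = classify_change(-pre, -post, thr_down)
        assert down is up

    def test_missing_level_errors(self):
        thr = _thresholds()
        del thr.rci[90]
        with pytest.raises(ValueError):
            classify_change(1, 2, thr, level=90)


class TestThresholdAssembly:
    def test_compute_thresholds(self):
        clin = DescriptiveStats(n=100, mean=51.14, sd=14.20)
        norm = DescriptiveStats(n=100, mean=61.72, sd=8.76)
        thr = compute_thresholds(clin, norm, r_xx=0.88)
        assert thr.se == pytest.approx(8.76 * np.sqrt(0.12), abs=1e-12)
        assert thr.rci[80] < thr.rci[90] < thr.rci[95]
        assert 51.14 < thr.cs < 61.72

    def test_rci_ordering_enforced(self):
        with pytest.raises(ValueError):
            ChangeThresholds(se=1.0, rci={80: 3.0, 90: 2.0, 95: 5.0}, cs=50.0)

    def test_dict_roundtrip(self):
        thr = _thresholds()
        back = ChangeThresholds.from_dict(thr.to_dict())
        assert back.cs == thr.cs and back.rci == thr.rci


class TestSeverityBands:
    def test_center_is_average(self):
        assert severity_band(50.0) == "Average"

    def test_cutpoint_goes_to_worse_side(self):
        assert severity_band(45.7) == "Below Average"
        assert severity_band(45.71) == "Average"

    def test_cs_boundary_transition(self):
        # the default clinical cutoff sits on the Below Average / Average edge
        assert severity_band(45.7 - 1e-9) == "Below Average"
        assert severity_band(45.7 + 1e-9) == "Average"

    def test_extremes(self):
        assert severity_band(20.0) == "Poor"
        assert severity_band(75.0) == "High"

    def test_lower_is_better_orientation(self):
        bands = SeverityBands(
            cutpoints=[40.0, 55.0],
            labels=["Mild", "Moderate", "Severe"],
            higher_is_better=False,
        )
        assert severity_band(30.0, bands) == "Mild"
        assert severity_band(40.0, bands) == "Moderate"  # tie goes to worse
        assert severity_band(60.0, bands) == "Severe"

    def test_unordered_cutpoints_rejected(self):
        with pytest.raises(ValueError):
            SeverityBands(cutpoints=[50.0, 40.0], labels=["a", "b", "c"])

    def test_default_bands_structure(self):
        assert len(DEFAULT_BANDS.labels) == len(DEFAULT_BANDS.cutpoints) + 1
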