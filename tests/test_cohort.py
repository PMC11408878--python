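"""Cohort generator: formulas, determinism, calibration of moments and
associations."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import lungwater as lw
from lungwater.cohort import (
    CohortParams,
    LogNormal,
    Normal,
    cohort_to_frame,
    compute_bsa,
    compute_gt,
    frame_to_cohort,
    sample_cohort,
)
from lungwater.errors import ParameterError


class TestBsa:
    def test_du_bois_value(self):
        assert compute_bsa(1.70, 70.0) == pytest.approx(1.81, abs=0.01)

    @given(
        h=st.floats(1.4, 2.1),
        w=st.floats(40.0, 140.0),
        dh=st.floats(0.01, 0.3),
        dw=st.floats(1.0, 40.0),
    )
    def test_strictly_increasing(self, h, w, dh, dw):
        base = compute_bsa(h, w)
        assert compute_bsa(h + dh, w) > base
        assert compute_bsa(h, w + dw) > base

    def test_ordering(self):
        assert compute_bsa(2.00, 100.0) > compute_bsa(1.70, 70.0)

    @pytest.mark.parametrize("h,w", [(0.0, 70.0), (1.7, 0.0), (-1.0, 70.0)])
    def test_invalid_inputs(self, h, w):
        with pytest.raises(ParameterError):
            compute_bsa(h, w)


class TestGlobalWallThickness:
    @pytest.mark.parametrize(
        "lvm,lvedv,expected",
        [(97.0, 134.0, 6.83), (76.0, 131.0, 5.62)],
    )
    def test_formula_values(self, lvm, lvedv, expected):
        # direct evaluation of 0.05 + 1.60 * LVM^0.84 * LVEDV^-0.49
        assert compute_gt(lvm, lvedv) == pytest.approx(expected, abs=0.02)

    def test_small_mass_limit(self):
        assert compute_gt(1e-8, 134.0) == pytest.approx(0.05, abs=1e-4)

    def test_invalid_inputs(self):
        with pytest.raises(ParameterError):
            compute_gt(0.0, 134.0)
        with pytest.raises(ParameterError):
            compute_gt(97.0, -1.0)


class TestSampling:
    def test_empty_cohort(self):
        assert sample_cohort(CohortParams.default(), 0, 0) == []

    def test_group_sizes_and_ids(self):
        subs = sample_cohort(CohortParams.default(seed=3), 4, 6)
        assert sum(s.group == "control" for s in subs) == 4
        assert sum(s.group == "at_risk" for s in subs) == 6
        assert len({s.id for s in subs}) == 10

    def test_same_seed_identical_different_seed_distinct(self):
        a = cohort_to_frame(sample_cohort(CohortParams.default(seed=5), 5, 5))
        b = cohort_to_frame(sample_cohort(CohortParams.default(seed=5), 5, 5))
        c = cohort_to_frame(sample_cohort(CohortParams.default(seed=6), 5, 5))
        assert a.equals(b)
        assert not a.drop(columns=["id", "group"]).equals(
            c.drop(columns=["id", "group"])
        )

    def test_subject_invariants(self):
        for s in sample_cohort(CohortParams.default(seed=1), 30, 30):
            assert s.bmi == pytest.approx(s.weight / s.height**2, rel=1e-9)
            assert 0 < s.true_lwd < 100
            assert s.true_lung_volume > 0
            assert s.bsa == pytest.approx(compute_bsa(s.height, s.weight), rel=1e-9)

    def test_negative_group_size_rejected(self):
        with pytest.raises(ParameterError):
            sample_cohort(CohortParams.default(), -1, 5)


@pytest.fixture(scope="module")
def big():
    subs = sample_cohort(CohortParams.default(seed=2), 5000, 5000)
    return cohort_to_frame(subs)


class TestCalibration:
    @pytest.mark.parametrize(
        "group,mean,sd",
        [("control", 27.2, 4.3), ("at_risk", 30.4, 5.0)],
    )
    def test_lwd_moments_within_two_mc_se(self, big, group, mean, sd):
        d = big.loc[big.group == group, "true_lwd"]
        n = len(d)
        assert abs(d.mean() - mean) <= 2 * sd / math.sqrt(n)
        assert abs(d.std() - sd) <= 2 * sd / math.sqrt(2 * n)

    def test_lognormal_medians(self, big):
        ctrl = big[big.group == "control"]
        risk = big[big.group == "at_risk"]
        assert np.median(ctrl.bmi) == pytest.approx(21.6, rel=0.02)
        assert np.median(risk.bmi) == pytest.approx(27.0, rel=0.02)
        assert np.median(ctrl.true_lung_volume) == pytest.approx(1861, rel=0.02)

    def test_lwd_bmi_association(self, big):
        """Within-group corr target sqrt(0.323) = 0.568, induced R2 0.323."""
        risk = big[big.group == "at_risk"]
        r = np.corrcoef(risk.true_lwd, risk.bmi)[0, 1]
        assert r == pytest.approx(math.sqrt(0.323), abs=0.02)
        assert r**2 == pytest.approx(0.323, abs=0.05)

    def test_lung_volume_bmi_inverse_association(self, big):
        risk = big[big.group == "at_risk"]
        r = np.corrcoef(risk.true_lung_volume, risk.bmi)[0, 1]
        assert r < 0
        assert r**2 == pytest.approx(0.09, abs=0.04)

    def test_lwv_tracks_body_size(self, big):
        """Emergent LWV is larger in males (size coupling)."""
        lwv = big.true_lwd / 100 * big.true_lung_volume
        assert lwv[big.sex == "M"].mean() > lwv[big.sex == "F"].mean()


class TestParams:
    def test_nonpositive_sd_rejected(self):
        p = CohortParams.default()
        bad = p.groups["control"].__class__(
            **{**p.groups["control"].__dict__, "lwd": Normal(27.2, 0.0)}
        )
        with pytest.raises(ParameterError):
            CohortParams(groups={"control": bad, "at_risk": p.groups["at_risk"]}).validate()

    def test_out_of_range_correlation_rejected(self):
        p = CohortParams.default()
        with pytest.raises(ParameterError):
            CohortParams(groups=p.groups, r_lwd_bmi=1.0).validate()

    def test_bad_quartiles_rejected(self):
        with pytest.raises(ParameterError):
            LogNormal(10.0, 12.0, 14.0).validate("x")

    def test_json_roundtrip(self):
        p = CohortParams.default(seed=9)
        q = CohortParams.from_json(p.to_json())
        assert q == p

    def test_csv_roundtrip(self, tmp_path):
        subs = sample_cohort(CohortParams.default(seed=4), 3, 3)
        f = tmp_path / "cohort.csv"
        cohort_to_frame(subs).to_csv(f, index=False)
        back = frame_to_cohort(pd.read_csv(f))
        assert [s.id for s in back] == [s.id for s in subs]
        assert back[0].true_lwd == pytest.approx(subs[0].true_lwd)
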