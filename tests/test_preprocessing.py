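"""Signal conditioning, QC rules, alignment and metadata encoding."""

import numpy as np
import pytest

from dualpath.cohort import Cohort, RoiTimeSeries, SubjectRecord
from dualpath.preprocess import (QcPolicy, SegmentSpec, apply_qc, age_stats_from,
                                 bandpass_filter, encode_metadata,
                                 hemodynamic_shift, regress_nuisance,
                                 slice_segment)


def _series(data, tr=0.8, sid="s0"):
    data = np.atleast_2d(data)
    return RoiTimeSeries(sid, data, tr, [f"r{i}" for i in range(data.shape[0])])


def _rec(sid, fd=0.1, rep=0.01, **kw):
    defaults = dict(diagnosis=0, age_years=11.0, sex="M", site="siteA")
    defaults.update(kw)
    return SubjectRecord(sid, defaults["diagnosis"], defaults["age_years"],
                         defaults["sex"], defaults["site"], fd, rep)


class TestQc:
    def _cohort(self):
        T = 30
        subs = []
        specs = [
            ("ok", 0.13, 0.02, False, 30),       # Table-1-like values pass
            ("fd", 0.6, 0.02, False, 30),
            ("rep", 0.1, 0.2, False, 30),
            ("nan", 0.1, 0.02, True, 30),
            ("shape", 0.1, 0.02, False, 25),
        ]
        for sid, fd, rep, with_nan, t in specs:
            d = np.random.default_rng(0).normal(size=(4, t))
            if with_nan:
                d[0, 0] = np.nan
            subs.append((_series(d, sid=sid), _rec(sid, fd, rep)))
        return Cohort(subs)

    def test_each_rule_triggers(self):
        cohort, report = apply_qc(self._cohort(), QcPolicy())
        assert cohort.subject_ids == ["ok"]
        assert len(report) == 4
        reasons = dict(zip(report["subject_id"], report["reasons"]))
        assert reasons["fd"] == "mean_fd"
        assert reasons["rep"] == "pct_repaired"
        assert "nan" in reasons["nan"]
        assert "shape_mismatch" in reasons["shape"]

    def test_boundary_fd_retained(self):
        subs = [(_series(np.zeros((2, 10)), sid="edge"), _rec("edge", fd=0.5)),
                (_series(np.zeros((2, 10)), sid="over"), _rec("over", fd=0.5000001))]
        cohort, report = apply_qc(Cohort(subs), QcPolicy())
        assert cohort.subject_ids == ["edge"]

    def test_empty_survivors_is_legal(self):
        subs = [(_series(np.zeros((2, 10)), sid="a"), _rec("a", fd=0.9))]
        cohort, report = apply_qc(Cohort(subs), QcPolicy())
        assert len(cohort) == 0 and len(report) == 1


class TestBandpass:
    def test_dc_rejected(self):
        ts = _series(np.full((3, 400), 7.0))
        out = bandpass_filter(ts)
        assert np.abs(out.data).max() < 1e-8 * 7.0

    def test_passband_sinusoid_preserved(self):
        tr, T = 0.8, 1000
        t = np.arange(T) * tr
        ts = _series(np.sin(2 * np.pi * 0.05 * t), tr=tr)
        out = bandpass_filter(ts)
        mid = slice(100, 900)  # avoid filter edge transients
        ratio = out.data[0, mid].std() / ts.data[0, mid].std()
        assert abs(ratio - 1) < 0.05

    def test_stopband_sinusoid_attenuated(self):
        tr, T = 0.8, 1000
        t = np.arange(T) * tr
        ts = _series(np.sin(2 * np.pi * 0.2 * t), tr=tr)
        out = bandpass_filter(ts)
        mid = slice(100, 900)  # exclude zero-phase edge transients
        assert out.data[0, mid].std() < 0.1 * ts.data[0, mid].std()

    def test_idempotent_on_in_band_signal(self):
        # for content inside the passband, refiltering changes energy < 1%
        tr, T = 0.8, 1200
        t = np.arange(T) * tr
        sig = sum(np.sin(2 * np.pi * f * t + i) for i, f in
                  enumerate([0.02, 0.04, 0.06]))
        ts = _series(np.vstack([sig, sig[::-1]]), tr=tr)
        once = bandpass_filter(ts)
        twice = bandpass_filter(once)
        mid = slice(150, 1050)
        e1 = np.sum(once.data[:, mid] ** 2)
        e2 = np.sum(twice.data[:, mid] ** 2)
        assert abs(e2 - e1) / e1 < 0.01

    def test_nyquist_violation_raises(self):
        ts = _series(np.zeros((1, 100)), tr=10.0)  # nyquist 0.05 Hz
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass_filter(ts, 0.008, 0.09)


class TestNuisanceRegression:
    def test_perfect_fit_gives_zero_residual(self):
        rng = np.random.default_rng(0)
        conf = rng.normal(size=(50, 1))
        ts = _series(3.0 * conf[:, 0] + 2.0)
        out = regress_nuisance(ts, conf)
        assert np.abs(out.data).max() < 1e-10

    def test_residuals_orthogonal_to_confounds(self):
        rng = np.random.default_rng(2)
        ts = _series(rng.normal(size=(4, 80)))
        conf = rng.normal(size=(80, 3))
        out = regress_nuisance(ts, conf)
        inner = out.data @ conf
        scale = np.abs(out.data).max() * np.abs(conf).max() * 80
        assert np.abs(inner).max() < 1e-6 * scale

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(3)
        ts = _series(rng.normal(size=(2, 60)))
        conf = rng.normal(size=(60, 2))
        X = np.column_stack([np.ones(60), conf])
        beta = np.linalg.solve(X.T @ X, X.T @ ts.data.T)
        expected = ts.data.T - X @ beta
        out = regress_nuisance(ts, conf)
        np.testing.assert_allclose(out.data, expected.T, atol=1e-10)

    def test_collinear_confounds_dropped_with_warning(self, caplog):
        rng = np.random.default_rng(4)
        ts = _series(rng.normal(size=(1, 40)))
        c = rng.normal(size=(40, 1))
        conf = np.column_stack([c, 2 * c])
        with caplog.at_level("WARNING"):
            out = regress_nuisance(ts, conf)
        assert "collinear" in caplog.text
        assert out.data.shape == ts.data.shape


class TestAlignment:
    @pytest.mark.parametrize("tr,delay,shift", [(0.8, 4.0, 5), (3.0, 4.0, 1),
                                                (2.0, 4.0, 2), (1.0, 0.0, 0)])
    def test_shift_rounding(self, tr, delay, shift):
        T = 50
        ts = _series(np.arange(T, dtype=float), tr=tr)
        out = hemodynamic_shift(ts, delay)
        assert out.n_timepoints == T - shift
        assert out.data[0, 0] == shift  # stimulus t=0 pairs with sample t=shift

    def test_shift_exceeding_length_raises(self):
        ts = _series(np.zeros(10), tr=1.0)
        with pytest.raises(ValueError):
            hemodynamic_shift(ts, 20.0)

    @pytest.mark.parametrize("start,end,T,width", [(372, 543, 600, 171),
                                                   (547, "end", 600, 53),
                                                   (0, "end", 600, 600)])
    def test_segment_widths(self, start, end, T, width):
        ts = _series(np.zeros((2, T)))
        out = slice_segment(ts, SegmentSpec("seg", start, end))
        assert out.n_timepoints == width


class TestMetadata:
    def test_definition(self):
        rec = _rec("a", sex="F", site="siteB", age_years=11.0)
        v = encode_metadata(rec, ["siteA", "siteB", "siteC"], (11.0, 1.5))
        np.testing.assert_allclose(v.values, [1, 0, 0, 1, 0, 0.0])

    def test_age_one_sd_above(self):
        rec = _rec("a", sex="M", site="siteA", age_years=12.5)
        v = encode_metadata(rec, ["siteA"], (11.0, 1.5))
        assert v.values[-1] == pytest.approx(1.0)
        assert len(v.values) == 2 + 1 + 1

    def test_four_sites_length_seven(self):
        rec = _rec("a", site="s4")
        v = encode_metadata(rec, ["s1", "s2", "s3", "s4"], (10.0, 2.0))
        assert len(v.values) == 7

    def test_unseen_site_raises(self):
        rec = _rec("a", site="elsewhere")
        with pytest.raises(ValueError, match="unseen site"):
            encode_metadata(rec, ["siteA"], (10.0, 2.0))

    def test_training_fold_statistics_only(self):
        # using different "training" records changes the encoding: the age
        # statistics must come from the training fold, not the subject itself
        rec = _rec("a", age_years=12.0)
        train_a = [_rec("t1", age_years=10.0), _rec("t2", age_years=14.0)]
        train_b = [_rec("t3", age_years=12.0), _rec("t4", age_years=12.5)]
        va = encode_metadata(rec, ["siteA"], age_stats_from(train_a))
        vb = encode_metadata(rec, ["siteA"], age_stats_from(train_b))
        assert va.values[-1] != vb.values[-1]
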