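import numpy as np
import pytest

from stridekit import evaluation as ev
from stridekit.types import GaitGroundTruth, StepDetections, StrictSCMetrics

from conftest import bruteforce_strict_counts


def detections(indices, scores=None):
    indices = np.asarray(indices, dtype=np.int64)
    if scores is None:
        scores = np.ones(indices.size)
    return StepDetections(indices, np.asarray(scores, dtype=float))


class TestWDError:
    def test_perfect_and_inverted(self):
        truth = np.array([1, 0, 1, 1, 0])
        assert ev.wd_error(truth, truth) == (0, 1.0)
        err, acc = ev.wd_error(1 - truth, truth)
        assert err == truth.size
        assert acc == 0.0

    def test_random_prediction_is_chance(self, rng):
        truth = rng.permutation([0, 1] * 500)
        pred = rng.integers(0, 2, size=1000)
        _, acc = ev.wd_error(pred, truth)
        assert abs(acc - 0.5) < 0.05


class TestSCError:
    @pytest.mark.parametrize(
        "cest,n,rel,loose",
        [(100, 100, 0.0, 0.0), (95, 100, 0.05, -5.0), (210, 100, 1.1, 110.0)],
    )
    def test_forced_values(self, cest, n, rel, loose):
        got_rel, got_loose = ev.sc_error(cest, n)
        assert got_rel == pytest.approx(rel)
        assert got_loose == pytest.approx(loose)

    def test_zero_truth_rejected(self):
        with pytest.raises(ValueError):
            ev.sc_error(10, 0)


class TestStrictMatch:
    CYCLES = GaitGroundTruth(np.array([[0, 100], [100, 200], [200, 300], [300, 400]]))

    def test_one_event_per_cycle(self):
        m = ev.strict_match(detections([50, 150, 250, 350]), self.CYCLES)
        assert (m.tpr, m.fpr) == (1.0, 0.0)

    def test_forced_2101_configuration(self):
        """Events per cycle [2, 1, 0, 1]: Ctp 3, Cfp 1, TPR 0.75, FPR 0.25."""
        m = ev.strict_match(detections([10, 60, 150, 350]), self.CYCLES)
        assert (m.ctp, m.cfp) == (3, 1)
        assert (m.tpr, m.fpr) == (0.75, 0.25)

    def test_outside_events_are_false_positives(self):
        m = ev.strict_match(detections([50, 150, 250, 350, 450, 500]), self.CYCLES)
        assert m.cfp == 2
        assert m.cest == m.ctp + m.cfp

    def test_matches_bruteforce_on_random_configs(self, rng):
        for _ in range(300):
            n_cycles = int(rng.integers(1, 20))
            edges = np.sort(rng.choice(np.arange(1, 1000), size=2 * n_cycles, replace=False))
            cycles = edges.reshape(-1, 2)
            truth = GaitGroundTruth(cycles)
            idx = np.unique(rng.integers(0, 1050, size=rng.integers(0, 40)))
            m = ev.strict_match(detections(idx), truth)
            ctp, cfp = bruteforce_strict_counts(idx, cycles)
            assert (m.ctp, m.cfp) == (ctp, cfp)
            assert m.ctp + m.misses == truth.cgt  # conservation

    def test_empty_truth_rejected(self):
        with pytest.raises(ValueError):
            ev.strict_match(detections([1]), GaitGroundTruth(np.empty((0, 2))))


class TestROC:
    CYCLES = GaitGroundTruth(np.array([[0, 100], [100, 200], [200, 300], [300, 400]]))

    def test_endpoints(self):
        det = detections([50, 150, 250, 380, 390], [5.0, 4.0, 3.0, 2.0, 1.0])
        curve = ev.roc_curve(det, self.CYCLES)
        assert (curve.fpr[0], curve.tpr[0]) == (0.0, 0.0)  # above max score
        assert curve.tpr[-1] == 1.0  # all events admitted
        assert curve.fpr[-1] == 0.25

    def test_monotone_in_both_rates(self, rng):
        idx = np.unique(rng.integers(0, 400, size=30))
        det = detections(idx, rng.normal(size=idx.size))
        curve = ev.roc_curve(det, self.CYCLES)
        assert np.all(np.diff(curve.thresholds) < 0)
        assert np.all(np.diff(curve.tpr) >= 0)
        assert np.all(np.diff(curve.fpr) >= 0)

    def test_operating_point_prefers_lower_fpr_on_ties(self):
        det = detections([50, 150, 250, 350], [4.0, 3.0, 2.0, 1.0])
        curve = ev.roc_curve(det, self.CYCLES)
        thr, fpr, _ = curve.operating_point(0.0)
        assert fpr == 0.0


class TestErrorSources:
    def mk(self, cfp):
        return StrictSCMetrics(ctp=5, cfp=cfp, cgt=10, cest=5 + cfp)

    def test_single_source(self):
        shares = ev.error_sources({"Hand": self.mk(4), "Foot": self.mk(0)})
        assert shares == {"Hand": 1.0, "Foot": 0.0}

    def test_uniform_sources(self):
        shares = ev.error_sources({p: self.mk(3) for p in ["A", "B", "C", "D"]})
        assert all(v == pytest.approx(0.25) for v in shares.values())
        assert sum(shares.values()) == pytest.approx(1.0)

    def test_no_false_positives_rejected(self):
        with pytest.raises(ValueError):
            ev.error_sources({"Hand": self.mk(0)})


class TestContextReport:
    def test_identical_context_zero_delta(self):
        df = ev.context_report(0.8, {"orientation": {"known": 0.8}})
        row = df[df.axis == "orientation"].iloc[0]
        assert row.delta == 0.0

    def test_range_rows(self):
        df = ev.context_report(0.8, {"placement": {"Foot": 0.9, "Hand": 0.7}})
        sub = df[df.axis == "placement"]
        assert set(sub.delta.round(6)) == {0.1, -0.1}
        assert np.allclose(sub.delta_min, -0.1)
        assert np.allclose(sub.delta_max, 0.1)

    def test_empty_axis_rejected(self):
        with pytest.raises(ValueError):
            ev.context_report(0.8, {"placement": {}})


def test_pooled_operating_point(rng):
    truth = GaitGroundTruth(np.arange(0, 1000, 100).reshape(-1, 2))
    dets, truths = [], []
    for _ in range(3):
        idx = np.unique(rng.integers(0, 1000, size=15))
        dets.append(detections(idx, rng.normal(size=idx.size)))
        truths.append(truth)
    tpr, fpr, thr = ev.pooled_tpr_at_fpr(dets, truths, 0.2)
    assert 0.0 <= tpr <= 1.0
    assert fpr >= 0.0
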