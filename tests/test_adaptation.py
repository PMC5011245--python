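import numpy as np
import pytest

from coadapt.adaptation import (
    CovarianceBank,
    PortionRecord,
    ThresholdState,
    balance_best,
    gate_feedback,
    schedule_arrows,
    select_best,
    u_accuracy,
    update_spatial_filter,
)
from coadapt.classification import Decision
from coadapt.csp import NormalizedCovariance, compute_csp

RIGHT, LEFT = "right", "left"


def rec(cue, predicted, distance, above=False):
    return PortionRecord(
        covariance=NormalizedCovariance(np.eye(2) / 2, label=cue),
        cue=cue,
        decision=Decision(predicted=predicted, distance=distance),
        above_threshold=above,
    )


class TestThresholds:
    def test_start_at_zero(self):
        st = ThresholdState()
        assert st.threshold(RIGHT) == 0.0 and st.threshold(LEFT) == 0.0

    def test_sixty_percent_of_mean_correct_distance(self):
        from coadapt.adaptation import update_threshold

        st = ThresholdState()
        for d in (1.0, 2.0, 3.0):
            update_threshold(st, rec(RIGHT, RIGHT, d))
        assert st.threshold(RIGHT) == pytest.approx(0.6 * 2.0)
        assert st.threshold(LEFT) == 0.0

    def test_misclassified_record_ignored(self):
        from coadapt.adaptation import update_threshold

        st = ThresholdState()
        update_threshold(st, rec(RIGHT, LEFT, 5.0))
        assert st.threshold(RIGHT) == 0.0 and st.threshold(LEFT) == 0.0

    def test_frozen_state_rejects_updates(self):
        from coadapt.adaptation import update_threshold

        st = ThresholdState(frozen=True)
        with pytest.raises(RuntimeError):
            update_threshold(st, rec(RIGHT, RIGHT, 1.0))

    def test_gate_zero_threshold_passes_any_nonzero(self):
        st = ThresholdState()
        assert gate_feedback(st, rec(LEFT, LEFT, -0.001))

    def test_gate_strict_inequality_at_boundary(self):
        from coadapt.adaptation import update_threshold

        st = ThresholdState()
        update_threshold(st, rec(RIGHT, RIGHT, 2.0))  # threshold now 1.2
        at_boundary = rec(RIGHT, RIGHT, 1.2)
        above = rec(RIGHT, RIGHT, 1.3)
        assert not gate_feedback(st, at_boundary)
        assert gate_feedback(st, above)
        assert at_boundary.above_threshold is False and above.above_threshold is True

    def test_gate_uses_predicted_class_threshold(self):
        from coadapt.adaptation import update_threshold

        st = ThresholdState()
        update_threshold(st, rec(RIGHT, RIGHT, 2.0))  # right threshold 1.2, left 0
        # predicted left with small distance passes (left threshold still 0)
        assert gate_feedback(st, rec(RIGHT, LEFT, -0.5))


class TestSelection:
    def test_all_incorrect_gives_empty_b(self):
        records = [rec(RIGHT, LEFT, 1.0, above=True) for _ in range(5)]
        assert select_best(records) == []

    def test_mixed_set_selects_both_flags(self):
        records = [
            rec(RIGHT, RIGHT, 1.0, above=True),   # keep
            rec(RIGHT, RIGHT, 1.0, above=False),  # below threshold
            rec(RIGHT, LEFT, -1.0, above=True),   # incorrect
            rec(LEFT, LEFT, -2.0, above=True),    # keep
            rec(LEFT, RIGHT, 2.0, above=True),    # incorrect
            rec(LEFT, LEFT, -0.5, above=True),    # keep
        ]
        b = select_best(records)
        assert len(b) == 3
        assert b == [records[0], records[3], records[5]]

    def test_all_qualify_identity(self):
        records = [rec(RIGHT, RIGHT, 1.0, above=True) for _ in range(4)]
        assert select_best(records) == records


class TestBalance:
    def test_majority_trimmed_by_smallest_distance(self):
        rights = [rec(RIGHT, RIGHT, d, above=True) for d in (0.5, 2.0, 0.1, 3.0, 1.0, 0.7)]
        lefts = [rec(LEFT, LEFT, -d, above=True) for d in (1.0, 2.0, 0.4, 0.9)]
        bb = balance_best(rights + lefts)
        bb_r = [r for r in bb if r.cue == RIGHT]
        assert len(bb_r) == 4 and sum(r.cue == LEFT for r in bb) == 4
        kept = sorted(abs(r.decision.distance) for r in bb_r)
        assert kept == [0.7, 1.0, 2.0, 3.0]  # 0.1 and 0.5 evicted

    def test_one_class_absent_gives_empty(self):
        assert balance_best([rec(RIGHT, RIGHT, 1.0, above=True)] * 3) == []

    def test_already_balanced_identity(self):
        b = [rec(RIGHT, RIGHT, 1.0, above=True), rec(LEFT, LEFT, -1.0, above=True)]
        assert balance_best(b) == b

    def test_bb_always_balanced_and_even(self, rng):
        for _ in range(20):
            b = [
                rec(
                    RIGHT if rng.random() < 0.5 else LEFT,
                    RIGHT if rng.random() < 0.5 else LEFT,
                    float(rng.normal()),
                    above=True,
                )
                for _ in range(int(rng.integers(0, 30)))
            ]
            b = [r for r in b if r.correct]
            bb = balance_best(b)
            n_r = sum(r.cue == RIGHT for r in bb)
            n_l = sum(r.cue == LEFT for r in bb)
            assert n_r == n_l and len(bb) % 2 == 0


class TestFilterUpdate:
    @staticmethod
    def _cov(rng, label):
        from test_csp import random_spd

        m = random_spd(rng, 3)
        return NormalizedCovariance(m / np.trace(m), label=label)

    def _bank(self, rng, n=6):
        bank = CovarianceBank()
        bank.extend([self._cov(rng, RIGHT if i % 2 == 0 else LEFT) for i in range(n)])
        return bank

    def test_empty_bb_leaves_w_unchanged(self, rng):
        bank = self._bank(rng)
        w_old = compute_csp(bank.class_mean(RIGHT), bank.class_mean(LEFT))
        w_new = update_spatial_filter(bank, [], w_old)
        assert w_new is w_old
        assert bank.count() == 6

    def test_duplicating_bank_mean_keeps_w(self, rng):
        bank = self._bank(rng)
        w_old = compute_csp(bank.class_mean(RIGHT), bank.class_mean(LEFT))
        bb = [
            PortionRecord(
                covariance=NormalizedCovariance(bank.class_mean(lab), label=lab),
                cue=lab,
                decision=Decision(lab, 1.0 if lab == RIGHT else -1.0),
                above_threshold=True,
            )
            for lab in (RIGHT, LEFT)
        ]
        w_new = update_spatial_filter(bank, bb, w_old)
        assert np.allclose(w_new.weights, w_old.weights, atol=1e-8)

    def test_sequential_equals_pooled(self, rng):
        covs = [self._cov(rng, RIGHT if i % 2 == 0 else LEFT) for i in range(12)]
        bank_seq = CovarianceBank()
        bank_seq.extend(covs[:6])
        w = compute_csp(bank_seq.class_mean(RIGHT), bank_seq.class_mean(LEFT))
        for k in (6, 8, 10):
            bb = [
                PortionRecord(covariance=c, cue=c.label,
                              decision=Decision(c.label, 1.0), above_threshold=True)
                for c in covs[k : k + 2]
            ]
            w = update_spatial_filter(bank_seq, bb, w)
        bank_pool = CovarianceBank()
        bank_pool.extend(covs)
        w_pool = compute_csp(bank_pool.class_mean(RIGHT), bank_pool.class_mean(LEFT))
        assert np.allclose(w.weights, w_pool.weights, atol=1e-10)

    def test_bank_class_mean_has_unit_trace(self, rng):
        bank = self._bank(rng, 10)
        assert np.isclose(np.trace(bank.class_mean(RIGHT)), 1.0, atol=1e-10)


class TestArrowSchedule:
    @pytest.mark.parametrize(
        "mis_r, mis_l, expected_r",
        [
            (10, 10, 5),  # symmetric
            (30, 0, 7),   # cap engaged
            (0, 30, 3),   # cap, other side
            (20, 10, 6),  # proportional floor
            (10, 20, 3),  # floor(3.33)
            (0, 0, 5),    # no errors -> balanced
        ],
    )
    def test_split(self, mis_r, mis_l, expected_r):
        s = schedule_arrows(mis_r, mis_l, 10)
        assert (s.arrows_right, s.arrows_left) == (expected_r, 10 - expected_r)

    def test_order_is_seeded_permutation(self):
        s1 = schedule_arrows(20, 10, 10, rng=np.random.default_rng(5))
        s2 = schedule_arrows(20, 10, 10, rng=np.random.default_rng(5))
        assert s1.order == s2.order
        assert sorted(s1.order) == [LEFT] * 4 + [RIGHT] * 6

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            schedule_arrows(-1, 0)


class TestUAccuracy:
    def test_all_correct(self):
        assert u_accuracy([rec(RIGHT, RIGHT, 1.0)] * 5) == 1.0

    def test_half_correct(self):
        records = [rec(RIGHT, RIGHT, 1.0)] * 85 + [rec(RIGHT, LEFT, -1.0)] * 85
        assert u_accuracy(records) == 0.5

    def test_threshold_independent(self):
        a = [rec(RIGHT, RIGHT, 1.0, above=True), rec(LEFT, RIGHT, 1.0, above=False)]
        b = [rec(RIGHT, RIGHT, 1.0, above=False), rec(LEFT, RIGHT, 1.0, above=True)]
        assert u_accuracy(a) == u_accuracy(b) == 0.5

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            u_accuracy([])
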