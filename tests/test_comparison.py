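import numpy as np
import pytest

import dcmnet as d


def _subjects(n):
    return tuple(f"S{i + 1:02d}" for i in range(n))


def model_columns():
    return tuple(str(i) for i in range(1, 13))


class TestFamilyPooling:
    def test_uniform_evidence_stays_uniform(self):
        ev = d.EvidenceMatrix(np.zeros((5, 12)), _subjects(5), model_columns())
        s1_fams, stim_fams = d.family_definitions()
        fam_ev = d.pool_family_evidence(ev, s1_fams)
        assert fam_ev.values.shape == (5, 4)
        assert np.allclose(fam_ev.values, fam_ev.values[0, 0])
        assert d.pool_family_evidence(ev, stim_fams).values.shape == (5, 3)

    def test_dominant_model_bound(self):
        vals = np.zeros((4, 12))
        vals[:, 10] = 25.0  # model 11 dominates by 25 nats
        ev = d.EvidenceMatrix(vals, _subjects(4), model_columns())
        s1_fams, _ = d.family_definitions()
        fam_ev = d.pool_family_evidence(ev, s1_fams).values
        lead = fam_ev[:, 3] - fam_ev[:, :3].max(axis=1)
        assert np.all(lead >= 25.0 - np.log(3) - np.log(3))

    def test_sessions_sum_before_pooling(self):
        a = d.EvidenceMatrix(np.full((3, 12), 1.0), _subjects(3), model_columns())
        b = d.EvidenceMatrix(np.full((3, 12), 2.0), _subjects(3), model_columns())
        pooled = d.pool_subject_evidence([a, b])
        assert np.allclose(pooled.values, 3.0)

    def test_missing_subject_rejected(self):
        a = d.EvidenceMatrix(np.zeros((3, 12)), _subjects(3), model_columns())
        b = d.EvidenceMatrix(np.zeros((2, 12)), _subjects(2), model_columns())
        with pytest.raises(ValueError, match="S03"):
            d.pool_subject_evidence([a, b])

    def test_non_finite_evidence_rejected(self):
        vals = np.zeros((2, 12))
        vals[0, 0] = np.inf
        with pytest.raises(ValueError, match="finite"):
            d.EvidenceMatrix(vals, _subjects(2), model_columns())


class TestRfxBms:
    def test_decisive_four_family_run(self):
        vals = np.tile([0.0, 0.0, 0.0, 20.0], (10, 1))
        ev = d.EvidenceMatrix(vals, _subjects(10), ("a", "b", "c", "d"))
        res = d.rfx_bms(ev)
        assert np.allclose(res.alpha, [1, 1, 1, 11], atol=1e-6)
        assert res.expected_p[3] == pytest.approx(11 / 14, abs=1e-6)
        assert res.expected_p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_symmetry_single_subject(self):
        ev = d.EvidenceMatrix(np.zeros((1, 3)), _subjects(1), ("a", "b", "c"))
        res = d.rfx_bms(ev)
        assert np.allclose(res.expected_p, 1 / 3)

    def test_alpha_conservation(self):
        rng = np.random.default_rng(0)
        ev = d.EvidenceMatrix(rng.normal(0, 3, (7, 4)), _subjects(7), ("a", "b", "c", "d"))
        res = d.rfx_bms(ev, alpha0=1.0)
        assert res.alpha.sum() == pytest.approx(4 + 7, abs=1e-6)

    def test_uniform_subject_less_decisive_than_informative_one(self):
        # a subject with flat evidence pulls the winner up less than a
        # decisive subject does (the variational scheme assigns ambiguous
        # subjects to families in proportion to current belief, so flat
        # evidence does not shrink the posterior toward uniformity)
        vals = np.tile([10.0, 0.0, 0.0], (5, 1))
        with_uniform = d.rfx_bms(
            d.EvidenceMatrix(np.vstack([vals, np.zeros(3)]), _subjects(6), ("a", "b", "c"))
        )
        with_decisive = d.rfx_bms(
            d.EvidenceMatrix(np.vstack([vals, [10.0, 0.0, 0.0]]), _subjects(6), ("a", "b", "c"))
        )
        assert with_uniform.expected_p[0] < with_decisive.expected_p[0]
        assert with_uniform.alpha.sum() == pytest.approx(with_decisive.alpha.sum(), abs=1e-3)


class TestExceedance:
    def test_symmetric_dirichlet(self):
        xp = d.exceedance(np.ones(4), n_samples=200_000, seed=0)
        se = np.sqrt(0.25 * 0.75 / 200_000)
        assert np.all(np.abs(xp - 0.25) < 3 * se + 1e-3)
        assert xp.sum() == pytest.approx(1.0)

    def test_decisive_posterior(self):
        xp = d.exceedance(np.array([11.0, 1.0, 1.0, 1.0]), n_samples=1_000_000, seed=1)
        assert xp[0] == pytest.approx(0.99854, abs=0.002)

    def test_seed_stability(self):
        alpha = np.array([11.0, 1.0, 1.0])
        a = d.exceedance(alpha, n_samples=1_000_000, seed=1)
        b = d.exceedance(alpha, n_samples=1_000_000, seed=2)
        assert np.max(np.abs(a - b)) < 0.002

    def test_input_validation(self):
        with pytest.raises(ValueError, match="positive"):
            d.exceedance(np.array([1.0, -1.0]), n_samples=200_000)
        with pytest.raises(ValueError, match="1e5"):
            d.exceedance(np.ones(3), n_samples=100)


class TestWinningModel:
    def _result(self, columns, expected):
        expected = np.asarray(expected, dtype=float)
        return d.BMSResult(
            alpha=expected * 10, expected_p=expected, exceedance_p=None, columns=columns
        )

    def test_intersection_of_winning_families(self):
        s1 = self._result(("F_S1_1", "F_S1_2", "F_S1_3", "F_S1_4"), [0.1, 0.1, 0.1, 0.7])
        stim = self._result(("F_stim_1", "F_stim_2", "F_stim_3"), [0.1, 0.8, 0.1])
        assert d.select_winning_model(s1, stim) == 11

    def test_first_families_give_model_one(self):
        s1 = self._result(("F_S1_1", "F_S1_2", "F_S1_3", "F_S1_4"), [0.7, 0.1, 0.1, 0.1])
        stim = self._result(("F_stim_1", "F_stim_2", "F_stim_3"), [0.8, 0.1, 0.1])
        assert d.select_winning_model(s1, stim) == 1

    def test_tie_rejected(self):
        s1 = self._result(("F_S1_1", "F_S1_2", "F_S1_3", "F_S1_4"), [0.4, 0.4, 0.1, 0.1])
        stim = self._result(("F_stim_1", "F_stim_2", "F_stim_3"), [0.8, 0.1, 0.1])
        with pytest.raises(ValueError, match="tie"):
            d.select_winning_model(s1, stim)
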