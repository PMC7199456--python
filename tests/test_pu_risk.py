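"""Cross-entropy, the three PU risk terms, the unbiased and clamped objectives.

Each operation is checked against an independently coded per-voxel loop
oracle computed in high precision with mpmath-free closed forms.
"""

import math

import numpy as np
import pytest

from boxsup3d import PULossConfig, naive_risk, nn_pu_risk, pu_risk, risk_components, voxel_ce
from boxsup3d.pu_risk import (
    RiskComponents,
    defensive_gradient,
    naive_gradient,
    pu_risk_gradient,
)

LN2 = math.log(2.0)


def _oracle_ce(logit, target):
    # independent formulation via the direct definition, stable enough for
    # the logit ranges exercised here
    p = 1.0 / (1.0 + math.exp(-min(max(logit, -700), 700)))
    if target == 1:
        return -math.log(p) if p > 0 else float("inf")
    return -math.log1p(-p) if p < 1 else float("inf")


class TestVoxelCE:
    def test_zero_logit_is_ln2(self):
        assert voxel_ce(0.0, 0) == pytest.approx(LN2, abs=1e-12)
        assert voxel_ce(0.0, 1) == pytest.approx(LN2, abs=1e-12)

    def test_saturated_correct_prediction_vanishes(self):
        assert voxel_ce(30.0, 1) < 1e-12
        assert voxel_ce(-30.0, 0) < 1e-12

    def test_unit_logit_wrong_class_is_softplus_one(self):
        assert voxel_ce(1.0, 0) == pytest.approx(np.logaddexp(0, 1.0), abs=1e-12)
        assert voxel_ce(1.0, 0) == pytest.approx(1.3132616875182228, abs=1e-12)

    def test_extreme_logits_finite(self):
        assert np.isfinite(voxel_ce(1e4, 0))
        assert np.isfinite(voxel_ce(-1e4, 1))

    def test_matches_oracle_on_moderate_logits(self, rng):
        logits = rng.normal(0, 5, 200)
        targets = rng.integers(0, 2, 200)
        for lo, t in zip(logits, targets):
            assert voxel_ce(lo, t) == pytest.approx(_oracle_ce(lo, t), abs=1e-9)


class TestRiskComponents:
    def test_all_zero_logits_give_ln2_components(self):
        logits = np.zeros(10)
        labels = np.array([0] * 4 + [1] * 6)
        c = risk_components(logits, labels)
        for term in (c.r_p_plus, c.r_u_minus, c.r_p_minus):
            assert term == pytest.approx(LN2, abs=1e-12)
        assert c.n_pos == 4 and c.n_unl == 6

    def test_two_voxel_saturated_case(self):
        c = risk_components(np.array([30.0, 30.0]), np.array([0, 1]))
        assert c.r_p_plus == pytest.approx(30.0, abs=1e-6)
        assert c.r_u_minus == pytest.approx(0.0, abs=1e-6)
        assert c.r_p_minus == pytest.approx(0.0, abs=1e-6)

    def test_single_class_batch_errors(self):
        with pytest.raises(ValueError, match="single label class"):
            risk_components(np.zeros(5), np.ones(5))

    def test_matches_loop_oracle(self, rng):
        logits = rng.normal(0, 3, 1000)
        labels = rng.integers(0, 2, 1000)
        c = risk_components(logits, labels)
        pp = [_oracle_ce(l, 0) for l, y in zip(logits, labels) if y == 0]
        um = [_oracle_ce(l, 1) for l, y in zip(logits, labels) if y == 1]
        pm = [_oracle_ce(l, 1) for l, y in zip(logits, labels) if y == 0]
        assert c.r_p_plus == pytest.approx(np.mean(pp), abs=1e-9)
        assert c.r_u_minus == pytest.approx(np.mean(um), abs=1e-9)
        assert c.r_p_minus == pytest.approx(np.mean(pm), abs=1e-9)

    def test_shared_n_divides_by_total(self):
        logits = np.array([1.0, -2.0, 0.5, 3.0])
        labels = np.array([0, 0, 1, 1])
        c = risk_components(logits, labels, shared_n=True)
        g = risk_components(logits, labels, shared_n=False)
        assert c.r_p_plus == pytest.approx(g.r_p_plus * 2 / 4)
        assert c.r_u_minus == pytest.approx(g.r_u_minus * 2 / 4)

    def test_permutation_invariance(self, rng):
        logits = rng.normal(0, 2, 64)
        labels = rng.integers(0, 2, 64)
        perm = rng.permutation(64)
        a = risk_components(logits, labels)
        b = risk_components(logits[perm], labels[perm])
        assert (a.n_pos, a.n_unl) == (b.n_pos, b.n_unl)
        assert a.r_p_plus == pytest.approx(b.r_p_plus, rel=1e-12)
        assert a.r_u_minus == pytest.approx(b.r_u_minus, rel=1e-12)
        assert a.r_p_minus == pytest.approx(b.r_p_minus, rel=1e-12)


class TestPURisk:
    CFG = PULossConfig(pi_p=0.75)

    def test_all_zero_logits_cancel_to_ln2(self):
        c = risk_components(np.zeros(8), np.array([0] * 4 + [1] * 4))
        assert pu_risk(c, self.CFG) == pytest.approx(LN2, abs=1e-12)

    def test_arithmetic_example(self):
        c = RiskComponents(1.0, 0.2, 0.8, 4, 4)
        assert pu_risk(c, self.CFG) == pytest.approx(0.35, abs=1e-12)

    def test_negative_when_correction_dominates(self):
        c = RiskComponents(0.0, 0.1, 0.8, 4, 4)
        assert pu_risk(c, self.CFG) < 0

    def test_nn_pu_equals_pu_when_clamp_inactive(self):
        c = RiskComponents(1.0, 0.9, 0.8, 4, 4)
        risk, flag = nn_pu_risk(c, self.CFG)
        assert risk == pytest.approx(pu_risk(c, self.CFG), abs=1e-15)
        assert not flag

    def test_nn_pu_clamped_case_with_flag(self):
        c = RiskComponents(1.0, 0.1, 0.8, 4, 4)
        risk, flag = nn_pu_risk(c, self.CFG)
        assert risk == pytest.approx(0.75, abs=1e-12)
        assert flag

    def test_nn_pu_nonnegative_for_beta_zero(self, rng):
        for _ in range(200):
            c = RiskComponents(*rng.uniform(0, 5, 3), 1, 1)
            risk, _ = nn_pu_risk(c, self.CFG)
            assert risk >= 0
            assert risk >= self.CFG.pi_p * c.r_p_plus

    def test_beta_widens_switch_tolerance(self):
        cfg = PULossConfig(pi_p=0.75, beta=0.2)
        c = RiskComponents(1.0, 0.5, 0.8, 4, 4)  # correction = -0.1 > -beta
        _, flag = nn_pu_risk(c, cfg)
        assert not flag

    def test_config_validation(self):
        with pytest.raises(ValueError):
            PULossConfig(pi_p=1.2)
        with pytest.raises(ValueError):
            PULossConfig(beta=0.9, pi_p=0.5)
        with pytest.raises(ValueError):
            PULossConfig(gamma=0.0)


class TestNaiveRisk:
    def test_zero_logits(self):
        assert naive_risk(np.zeros(7), np.array([0, 1] * 3 + [0])) == pytest.approx(LN2)

    def test_perfect_separation_vanishes(self):
        labels = np.array([0, 1, 0, 1])
        logits = np.where(labels == 1, 30.0, -30.0)
        assert naive_risk(logits, labels) < 1e-12

    def test_matches_loop_oracle(self, rng):
        logits = rng.normal(0, 3, 1000)
        labels = rng.integers(0, 2, 1000)
        expected = np.mean([_oracle_ce(l, y) for l, y in zip(logits, labels)])
        assert naive_risk(logits, labels) == pytest.approx(expected, abs=1e-9)


class TestGradients:
    """Analytic logit gradients agree with central differences of the risks."""

    @pytest.mark.parametrize("which", ["pu", "defensive", "naive"])
    def test_gradient_matches_finite_differences(self, which, rng):
        cfg = PULossConfig(pi_p=0.6)
        logits = rng.normal(0, 2, 40)
        labels = np.array([0] * 20 + [1] * 20)

        def value(lg):
            c = risk_components(lg, labels)
            if which == "pu":
                return pu_risk(c, cfg)
            if which == "defensive":
                return cfg.pi_p * c.r_p_minus - c.r_u_minus
            return naive_risk(lg, labels)

        if which == "pu":
            g = pu_risk_gradient(logits, labels, cfg)
        elif which == "defensive":
            g = defensive_gradient(logits, labels, cfg)
        else:
            g = naive_gradient(logits, labels)
        eps = 1e-6
        for i in range(0, 40, 7):
            lp = logits.copy()
            lp[i] += eps
            lm = logits.copy()
            lm[i] -= eps
            num = (value(lp) - value(lm)) / (2 * eps)
            assert g[i] == pytest.approx(num, abs=1e-6)


def test_unbiasedness_of_pu_estimator(rng):
    """With the true class prior, the PU risk is an unbiased estimate of the
    fully supervised risk pi_p*Rp+ + (1-pi_p)*Rn- of a fixed classifier."""
    pi_p = 0.7
    n_pop = 20000
    labels_true = (rng.random(n_pop) >= pi_p).astype(int)  # 1 = negative/tumor
    # fixed random "classifier": informative but imperfect logits
    logits = rng.normal(0, 1, n_pop) + 1.5 * labels_true - 0.75
    cfg = PULossConfig(pi_p=pi_p)

    sup = pi_p * np.mean(voxel_ce(logits[labels_true == 0], 0)) + (1 - pi_p) * np.mean(
        voxel_ce(logits[labels_true == 1], 1)
    )
    batch, n_resample = 400, 500
    vals = np.empty(n_resample)
    for b in range(n_resample):
        pos_idx = rng.choice(np.flatnonzero(labels_true == 0), size=batch)
        unl_idx = rng.choice(n_pop, size=batch)  # unlabeled = draws from marginal
        lg = np.concatenate([logits[pos_idx], logits[unl_idx]])
        lb = np.concatenate([np.zeros(batch, int), np.ones(batch, int)])
        vals[b] = pu_risk(risk_components(lg, lb), cfg)
    mc_se = vals.std(ddof=1) / math.sqrt(n_resample)
    assert abs(vals.mean() - sup) < 3 * mc_se
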