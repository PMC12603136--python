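"""Forward-model unit and property tests."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hdxcp.model import (
    ChainState,
    Hyperparameters,
    KineticParams,
    Peptide,
    PeptideTable,
    exchangeable_residues,
    log_likelihood,
    log_prior,
    predict_peptide_uptake,
    residue_uptake,
    segment_indices,
    segment_lookup,
)

params_st = st.builds(
    KineticParams,
    pi=st.floats(1e-3, 1 - 1e-3),
    p=st.floats(1e-3, 1 - 1e-3),
    b=st.floats(1e-6, 10.0),
    d=st.floats(1e-6, 10.0),
)


class TestExchangeableResidues:
    def test_plain_window(self):
        # first two residues dropped, end-exclusive
        assert exchangeable_residues(10, 20, "A" * 11) == set(range(12, 20))

    def test_proline_excluded(self):
        seq = list("A" * 11)
        seq[15 - 10] = "P"
        assert exchangeable_residues(10, 20, "".join(seq)) == \
            {12, 13, 14, 16, 17, 18, 19}

    def test_short_peptide_non_informative(self):
        # (10, 12): start+2 = 12 but the bound is end-exclusive -> empty
        assert exchangeable_residues(10, 12, "AAA") == set()
        pep = Peptide(id="x", sequence="AAA", start=10, end=12)
        assert not pep.informative

    def test_inclusive_end_switch(self):
        assert exchangeable_residues(10, 12, "AAA", inclusive_end=True) == {12}

    def test_invalid_coordinates(self):
        with pytest.raises(ValueError):
            exchangeable_residues(5, 5, "A")
        with pytest.raises(ValueError):
            exchangeable_residues(1, 4, "AA")


class TestResidueUptake:
    def test_zero_at_zero(self):
        assert residue_uptake(KineticParams(0.3, 0.5, 0.1, 0.2), 0.0) == 0.0

    def test_exponential_branch(self):
        # pi -> 1 leaves the single-exponential CDF
        p = KineticParams(1 - 1e-12, 0.5, 1.0, 0.1)
        assert residue_uptake(p, 10.0) == pytest.approx(1 - math.exp(-1), rel=1e-6)

    def test_mixture_collapse(self):
        # p -> 1 and b = d: both branches coincide with a single exponential
        p = KineticParams(0.5, 1 - 1e-12, 0.2, 0.2)
        t = np.array([1.0, 5.0, 40.0])
        np.testing.assert_allclose(residue_uptake(p, t), -np.expm1(-0.2 * t),
                                   rtol=1e-9)

    @given(params_st)
    @settings(max_examples=100, deadline=None)
    def test_monotone_bounded(self, kp):
        t = np.logspace(-3, 6, 60)
        u = residue_uptake(kp, t)
        assert np.all(np.diff(u) >= -1e-12)
        assert np.all(u >= 0) and np.all(u < 1 + 1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            residue_uptake(KineticParams(0.5, 0.5, 1, 1), -1.0)


def _random_state(rng, R, K):
    tau = np.sort(rng.uniform(1, R, K))
    theta = np.column_stack([
        rng.uniform(0.1, 0.9, K + 1), rng.uniform(0.1, 0.9, K + 1),
        rng.uniform(1e-4, 1, K + 1), rng.uniform(1e-4, 1, K + 1)])
    return ChainState(tau=tau, theta=theta, log_sigma=-3.0)


class TestSegmentLookup:
    def test_no_changepoints(self):
        st_ = _random_state(np.random.default_rng(0), 20, 0)
        for r in (1, 10, 20):
            assert segment_lookup(st_, r).as_array() == pytest.approx(st_.theta[0])

    def test_boundary_indicator(self):
        st_ = _random_state(np.random.default_rng(1), 20, 0)
        st_ = ChainState(tau=np.array([10.5]),
                         theta=np.vstack([st_.theta, st_.theta[0] * 0.5 + 0.25]),
                         log_sigma=-3.0)
        assert segment_lookup(st_, 10).as_array() == pytest.approx(st_.theta[0])
        assert segment_lookup(st_, 11).as_array() == pytest.approx(st_.theta[1])

    def test_step_function_brute_force(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            K = int(rng.integers(0, 6))
            st_ = _random_state(rng, 30, K)
            seg = segment_indices(st_.tau, 30)
            # independent loop oracle over the definition tau_{k-1} <= r < tau_k
            tau_ext = np.concatenate([[1.0], st_.tau, [31.0]])
            for r in range(1, 31):
                k = next(k for k in range(K + 1)
                         if tau_ext[k] <= r < tau_ext[k + 1])
                assert seg[r - 1] == k
            assert int(np.sum(np.diff(seg) != 0)) == len(set(
                np.searchsorted(st_.tau, np.arange(1, 31), side="right"))) - 1


class TestPredictPeptideUptake:
    def test_identical_residues(self):
        st_ = _random_state(np.random.default_rng(3), 20, 0)
        pep = Peptide(id="x", sequence="A" * 8, start=3, end=10)  # l = 5
        t = 150.0
        mu = residue_uptake(KineticParams(*st_.theta[0]), t)
        assert predict_peptide_uptake(st_, pep, t) == pytest.approx(5 * mu)

    def test_zero_at_time_zero(self):
        st_ = _random_state(np.random.default_rng(4), 20, 2)
        pep = Peptide(id="x", sequence="A" * 8, start=3, end=10)
        assert predict_peptide_uptake(st_, pep, 0.0) == pytest.approx(0.0)

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            st_ = _random_state(rng, 25, int(rng.integers(0, 4)))
            pep = Peptide(id="x", sequence="APAAAPAAA", start=5, end=13)
            t = np.array([15.0, 1500.0])
            manual = sum(residue_uptake(segment_lookup(st_, r), t)
                         for r in pep.exch)
            np.testing.assert_allclose(predict_peptide_uptake(st_, pep, t),
                                       manual, rtol=1e-12)


class TestLogLikelihood:
    def _table(self, peptides, rows):
        return PeptideTable(peptides, pd.DataFrame(
            rows, columns=["peptide", "state", "time", "replicate", "uptake"]))

    def test_zero_residual_mode_density(self, toy_peptides):
        st_ = _random_state(np.random.default_rng(6), 10, 0)
        pep = toy_peptides[0]                     # l = 3
        t = 150.0
        mu = float(predict_peptide_uptake(st_, pep, t))
        tab = self._table([pep], [("a", "s", t, 1, mu / pep.l)])
        scale = pep.l * st_.sigma ** 2
        assert log_likelihood(st_, tab) == pytest.approx(-math.log(2 * scale))

    def test_monotone_in_residuals(self, toy_peptides):
        st_ = _random_state(np.random.default_rng(7), 10, 0)
        pep = toy_peptides[0]
        t = 150.0
        mu = float(predict_peptide_uptake(st_, pep, t)) / pep.l
        ll = [log_likelihood(st_, self._table([pep], [("a", "s", t, 1, mu + d)]))
              for d in (0.05, 0.1)]
        assert ll[1] < ll[0]

    def test_hand_computed_toy(self):
        peptides = [
            Peptide(id="p1", sequence="AAAAA", start=1, end=5),   # exch {3,4}
            Peptide(id="p2", sequence="AAAA", start=2, end=5),    # exch {4}
            Peptide(id="p3", sequence="AAAAAA", start=1, end=6),  # exch {3,4,5}
        ]
        st_ = _random_state(np.random.default_rng(8), 6, 1)
        rows = [("p1", "s", 15.0, 1, 0.4), ("p2", "s", 15.0, 1, 0.9),
                ("p3", "s", 150.0, 1, 0.2)]
        tab = self._table(peptides, rows)
        expected = 0.0
        for pid, t, frac in [("p1", 15.0, 0.4), ("p2", 15.0, 0.9),
                             ("p3", 150.0, 0.2)]:
            pep = next(p for p in peptides if p.id == pid)
            mu = float(predict_peptide_uptake(st_, pep, t))
            scale = pep.l * st_.sigma ** 2
            expected += -abs(frac * pep.l - mu) / scale - math.log(2 * scale)
        assert log_likelihood(st_, tab) == pytest.approx(expected, rel=1e-12)


class TestLogPrior:
    def test_assembled_density_k1(self):
        # Pois(1; 3) term plus the tau term log(1/100) for R = 101, K = 1
        h = Hyperparameters(lam=3.0)
        st1 = _random_state(np.random.default_rng(9), 101, 1)
        assert log_prior(st1, h, 101) == pytest.approx(
            (-3.0 + math.log(3.0))
            + math.log(1 / 100)
            + sum(_theta_lp(row, st1) for row in st1.theta)
            + _sigma_hyper_lp(st1, h))

    def test_tau_term_k2(self):
        h = Hyperparameters(lam=1.0)
        rng = np.random.default_rng(10)
        st2 = _random_state(rng, 11, 2)
        st0 = ChainState(tau=np.empty(0), theta=st2.theta[:1],
                         log_sigma=st2.log_sigma)
        diff = (log_prior(st2, h, 11) - log_prior(st0, h, 11)
                - sum(_theta_lp(row, st2) for row in st2.theta[1:]))
        # Pois ratio log(lam^2/2!) plus tau term log(2!/10^2)
        assert diff == pytest.approx(math.log(1.0 / 2.0) + math.log(0.02))

    def test_out_of_support(self):
        h = Hyperparameters()
        st_ = ChainState(tau=np.array([0.5]),
                         theta=np.tile([0.5, 0.5, 1.0, 1.0], (2, 1)),
                         log_sigma=-3.0)
        assert log_prior(st_, h, 20) == -np.inf

    def test_normalizes_over_k(self):
        # summing exp(log prior) over K with fixed continuous parts
        # reduces to the Poisson pmf summing to 1
        lam = 2.5
        total = sum(math.exp(-lam + K * math.log(lam) - math.lgamma(K + 1))
                    for K in range(51))
        assert total == pytest.approx(1.0, abs=1e-12)


def _theta_lp(row, st_):
    # Beta(1,1) priors are flat; Gamma(1, rate) is rate * exp(-rate x)
    pi, p, b, d = row
    return (math.log(st_.b_rate) - st_.b_rate * b
            + math.log(st_.d_rate) - st_.d_rate * d)


def _sigma_hyper_lp(st_, h):
    return (-0.5 * ((st_.log_sigma - h.sigma_m) / h.sigma_v) ** 2
            - math.log(h.sigma_v) - 0.5 * math.log(2 * math.pi)
            + math.log(h.d_beta) - h.d_beta * st_.d_rate
            + math.log(h.b_beta) - h.b_beta * st_.b_rate)


class TestPeptideTable:
    def test_duplicate_observation_rejected(self, toy_peptides):
        df = pd.DataFrame([("a", "s", 15.0, 1, 0.5), ("a", "s", 15.0, 1, 0.6)],
                          columns=["peptide", "state", "time", "replicate",
                                   "uptake"])
        with pytest.raises(ValueError, match="duplicate"):
            PeptideTable(toy_peptides, df)

    def test_unknown_peptide_rejected(self, toy_peptides):
        df = pd.DataFrame([("zzz", "s", 15.0, 1, 0.5)],
                          columns=["peptide", "state", "time", "replicate",
                                   "uptake"])
        with pytest.raises(ValueError, match="unknown"):
            PeptideTable(toy_peptides, df)

    def test_redundancy_counts(self, toy_peptides):
        df = pd.DataFrame([("a", "s", 15.0, 1, 0.5), ("b", "s", 15.0, 1, 0.5)],
                          columns=["peptide", "state", "time", "replicate",
                                   "uptake"])
        tab = PeptideTable(toy_peptides, df, n_residues=7)
        np.testing.assert_array_equal(tab.redundancy(),
                                      [0, 0, 1, 1, 1, 1, 0])
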