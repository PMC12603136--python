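"""Reconstruction errors, effect probabilities, EFDR and differential calls."""

import numpy as np
import pandas as pd
import pytest

from hdxcp.model import (
    ChainState,
    Peptide,
    PeptideTable,
    coupling_matrix,
    residue_uptake_matrix,
)
from hdxcp.sampler import PosteriorSamples, SamplerConfig
from hdxcp.stats import (
    differential_tre,
    efdr,
    efdr_threshold,
    effect_probabilities,
    reconstruction_errors,
    residue_errors,
)

TIMES = np.array([15.0, 150.0])


def _samples_from_state(state, R, times=TIMES):
    draw = residue_uptake_matrix(state, R, times)
    return PosteriorSamples(
        states=[state], residue_uptake_draws=draw[None], times=np.asarray(times),
        n_residues=R, acceptance={"birth": (0, 1)},
        config=SamplerConfig(n_iter=2, burn_in=1), seed=0)


def _state(R, seed=0, K=0):
    rng = np.random.default_rng(seed)
    tau = np.sort(rng.uniform(1, R, K))
    theta = np.column_stack([rng.uniform(0.2, 0.8, K + 1),
                             rng.uniform(0.2, 0.8, K + 1),
                             rng.uniform(1e-3, 0.1, K + 1),
                             rng.uniform(1e-3, 0.1, K + 1)])
    return ChainState(tau=tau, theta=theta, log_sigma=-3.0)


def _table(peptides, rows, R=None):
    return PeptideTable(peptides, pd.DataFrame(
        rows, columns=["peptide", "state", "time", "replicate", "uptake"]),
        n_residues=R)


@pytest.fixture
def two_peptides():
    return [Peptide(id="p1", sequence="A" * 8, start=1, end=8),   # exch {3..7}
            Peptide(id="p2", sequence="A" * 6, start=3, end=8)]   # exch {5..7}


class TestReconstructionErrors:
    def test_perfect_fit_zero(self, two_peptides):
        st = _state(8)
        sam = _samples_from_state(st, 8)
        C = coupling_matrix(two_peptides, 8)
        P = C @ residue_uptake_matrix(st, 8, TIMES)
        rows = [(p.id, "s", t, 1, P[i, m] / p.l)
                for i, p in enumerate(two_peptides)
                for m, t in enumerate(TIMES)]
        re = reconstruction_errors(sam, _table(two_peptides, rows))
        np.testing.assert_allclose(re["re"], 0.0, atol=1e-12)

    def test_offset_shifts_linearly(self, two_peptides):
        st = _state(8)
        sam = _samples_from_state(st, 8)
        C = coupling_matrix(two_peptides, 8)
        P = C @ residue_uptake_matrix(st, 8, TIMES)
        delta = 0.07
        for i, p in enumerate(two_peptides):
            rows0 = [(p.id, "s", t, 1, P[i, m] / p.l) for m, t in enumerate(TIMES)]
            rows1 = [(p.id, "s", t, 1, P[i, m] / p.l + delta / p.l)
                     for m, t in enumerate(TIMES)]
            re0 = reconstruction_errors(sam, _table([p], rows0, R=8))
            re1 = reconstruction_errors(sam, _table([p], rows1, R=8))
            np.testing.assert_allclose(re1["re"] - re0["re"], delta, rtol=1e-9)

    def test_hand_computed_toy(self, two_peptides):
        st = _state(8)
        sam = _samples_from_state(st, 8)
        C = coupling_matrix(two_peptides, 8)
        P = C @ residue_uptake_matrix(st, 8, TIMES)
        rows = [("p1", "s", 15.0, 1, 0.30), ("p2", "s", 15.0, 1, 0.60)]
        re = reconstruction_errors(sam, _table(two_peptides, rows, R=8))
        l1, l2 = two_peptides[0].l, two_peptides[1].l
        np.testing.assert_allclose(
            re["re"].to_numpy(),
            [0.30 * l1 - P[0, 0], 0.60 * l2 - P[1, 0]], rtol=1e-12)


class TestResidueErrors:
    def _re_frame(self, values):
        # values: dict peptide -> normalized RE (single time 15.0)
        return pd.DataFrame(
            [(pid, 15.0, 1, v) for pid, v in values.items()],
            columns=["peptide", "time", "replicate", "re_norm"])

    def test_consistent_direction_amplifies(self, two_peptides):
        df = self._re_frame({"p1": 0.1, "p2": 0.1})
        res = residue_errors(df, two_peptides, 8)
        shared = res[(res["residue"] == 5)].iloc[0]   # covered by both
        assert shared["n"] == 2
        assert shared["signed_are"] == pytest.approx(0.1)
        assert shared["are"] == pytest.approx(0.1)
        assert shared["tre"] == pytest.approx(0.2)

    def test_opposite_signs_cancel(self, two_peptides):
        df = self._re_frame({"p1": 0.1, "p2": -0.1})
        res = residue_errors(df, two_peptides, 8)
        shared = res[(res["residue"] == 5)].iloc[0]
        assert shared["signed_are"] == pytest.approx(0.0, abs=1e-15)
        assert shared["are"] == pytest.approx(0.1)
        assert shared["tre"] == pytest.approx(0.0, abs=1e-15)

    def test_uncovered_residue_is_missing(self, two_peptides):
        df = self._re_frame({"p1": 0.1, "p2": 0.1})
        res = residue_errors(df, two_peptides, 8)
        r1 = res[res["residue"] == 1].iloc[0]
        assert r1["n"] == 0 and np.isnan(r1["tre"])

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        peptides = [Peptide(id=f"q{i}", sequence="A" * 9,
                            start=s, end=s + 8)
                    for i, s in enumerate(rng.integers(1, 12, 6))]
        vals = {p.id: float(rng.normal()) for p in peptides}
        df = self._re_frame(vals)
        res = residue_errors(df, peptides, 20)
        for r in range(1, 21):
            cover = [p for p in peptides if r in p.exch]
            row = res[res["residue"] == r].iloc[0]
            if not cover:
                assert np.isnan(row["tre"])
                continue
            manual = [vals[p.id] for p in cover]
            assert row["tre"] == pytest.approx(np.sum(manual))
            assert row["signed_are"] == pytest.approx(np.mean(manual))
            assert row["are"] == pytest.approx(np.mean(np.abs(manual)))


class TestEffectProbabilities:
    def test_zero_effect_zero_probability(self):
        p = effect_probabilities(np.zeros(3), np.array([2, 3, 4]),
                                 np.full(50, 0.1),
                                 rng=np.random.default_rng(0))
        np.testing.assert_array_equal(p, 0.0)

    def test_huge_effect_probability_one(self):
        p = effect_probabilities(np.full(2, 1e6), np.array([2, 3]),
                                 np.full(50, 0.1),
                                 rng=np.random.default_rng(0))
        np.testing.assert_array_equal(p, 1.0)

    def test_monotone_in_effect(self):
        sig = np.full(200, 0.05)
        vals = np.linspace(0, 0.5, 8)
        p = effect_probabilities(vals, np.full(8, 3), sig,
                                 rng=np.random.default_rng(1), inner=20)
        assert np.all(np.diff(p) >= 0)

    def test_matches_brute_force_null(self):
        # the null for TRE is a sum of n_r Laplace(0, sigma) draws; compare
        # with a large direct Monte-Carlo estimate of the same probability
        sigma, n_r, value = 0.05, 4, 0.25
        rng = np.random.default_rng(2)
        big = rng.laplace(0, sigma, size=(10 ** 6, n_r)).sum(axis=1)
        truth = float(np.mean(np.abs(value) > np.abs(big)))
        p = effect_probabilities(np.array([value]), np.array([n_r]),
                                 np.full(400, sigma),
                                 rng=np.random.default_rng(3), inner=50)[0]
        se = np.sqrt(truth * (1 - truth) / (400 * 50))
        assert p == pytest.approx(truth, abs=max(3 * se, 3e-3))


class TestEfdr:
    def test_arithmetic_example(self):
        probs = np.array([0.99, 0.95, 0.6])
        assert efdr(probs, 0.95) == pytest.approx((0.01 + 0.05) / 2)

    def test_all_ones_zero(self):
        assert efdr(np.ones(5), 0.9) == 0.0

    def test_no_call_signalled(self):
        with pytest.raises(ValueError):
            efdr(np.array([0.1, 0.2]), 0.9)

    def test_threshold_matches_exhaustive_scan(self):
        rng = np.random.default_rng(4)
        probs = rng.uniform(size=40) ** 0.3
        level = 0.05
        # brute force: smallest observed p with EFDR < level at it and at
        # every larger observed p
        obs = np.sort(np.unique(probs))[::-1]
        best = None
        for i, cand in enumerate(obs):
            if all(efdr(probs, q) < level for q in obs[:i + 1]):
                best = cand
            else:
                break
        assert efdr_threshold(probs, level) == best


class TestDifferential:
    def test_null_no_calls(self, two_peptides):
        st = _state(8)
        sam = _samples_from_state(st, 8)
        C = coupling_matrix(two_peptides, 8)
        P = C @ residue_uptake_matrix(st, 8, TIMES)
        noise = np.random.default_rng(5).normal(0, 1e-4, P.shape)
        rows = [(p.id, "apo", t, 1, (P[i, m] + noise[i, m]) / p.l)
                for i, p in enumerate(two_peptides)
                for m, t in enumerate(TIMES)]
        res = differential_tre(sam, _table(two_peptides, rows, R=8),
                               rng=np.random.default_rng(6))
        assert np.nanmax(np.abs(res["tre"])) < 0.01
        assert not res["efdr_call"].any()

    def test_protection_sign_convention(self, two_peptides):
        # reference uptake above the model prediction => the fitted state is
        # protected relative to the reference => negative TRE
        st = _state(8)
        sam = _samples_from_state(st, 8)
        C = coupling_matrix(two_peptides, 8)
        P = C @ residue_uptake_matrix(st, 8, TIMES)
        rows = [(p.id, "apo", t, 1, 1.25 * P[i, m] / p.l)
                for i, p in enumerate(two_peptides)
                for m, t in enumerate(TIMES)]
        res = differential_tre(sam, _table(two_peptides, rows, R=8),
                               rng=np.random.default_rng(7))
        covered = res[res["n"] > 0]
        assert (covered["tre"] < 0).all()

    def test_swap_flips_sign(self, two_peptides):
        st = _state(8)
        sam = _samples_from_state(st, 8)
        C = coupling_matrix(two_peptides, 8)
        P = C @ residue_uptake_matrix(st, 8, TIMES)
        up = [(p.id, "apo", t, 1, 1.2 * P[i, m] / p.l)
              for i, p in enumerate(two_peptides) for m, t in enumerate(TIMES)]
        down = [(p.id, "apo", t, 1, (2 * P[i, m] - 1.2 * P[i, m]) / p.l)
                for i, p in enumerate(two_peptides) for m, t in enumerate(TIMES)]
        r_up = differential_tre(sam, _table(two_peptides, up, R=8),
                                rng=np.random.default_rng(8))
        r_dn = differential_tre(sam, _table(two_peptides, down, R=8),
                                rng=np.random.default_rng(8))
        np.testing.assert_allclose(r_up["tre"].to_numpy(dtype=float),
                                   -r_dn["tre"].to_numpy(dtype=float),
                                   atol=1e-10)
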