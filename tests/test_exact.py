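"""Exact absorbing-chain solver: splitting, distributions, moments."""

import math

import numpy as np
import pytest

from polytrans.exact import (
    Chain1D,
    absorption_time_distribution,
    build_chain,
    classify_exact,
    mean_first_passage,
    splitting_probability,
)
from polytrans.pore import Direction, build_landscape
from polytrans.sequences import ChargeSequence


@pytest.fixture(scope="module")
def flat_chain(flat_profile):
    seq = ChargeSequence((1,) * 20, "flat")
    return build_chain(build_landscape(seq, Direction.CIS_TO_TRANS, flat_profile))


@pytest.fixture(scope="module")
def bench_chains(bench):
    return {
        label: build_chain(build_landscape(r.sequence, Direction.CIS_TO_TRANS))
        for label, r in bench.items()
    }


def _dense_splitting(chain):
    """Oracle: solve the (I - T) linear system for hit-right probabilities."""
    n = chain.n_states
    p, q, stay = chain.p, chain.q, chain.stay
    T = np.diag(stay)
    for i in range(n - 1):
        T[i, i + 1] = p[i]
        T[i + 1, i] = q[i + 1]
    b = np.zeros(n)
    b[-1] = p[-1]
    return np.linalg.solve(np.eye(n) - T, b)


class TestChainConstruction:
    def test_flat_landscape_is_symmetric_walk(self, flat_chain):
        np.testing.assert_allclose(flat_chain.p, 0.5)
        np.testing.assert_allclose(flat_chain.q, 0.5)
        np.testing.assert_allclose(flat_chain.stay, 0.0, atol=1e-15)

    def test_metropolis_rule_reproduced_independently(self, bench_chains, bench):
        # oracle: recompute 0.5*min(1, exp(-dE)) from the raw energy table
        land = build_landscape(bench["e"].sequence, Direction.CIS_TO_TRANS)
        chain = bench_chains["e"]
        E = land.energies
        for j in range(chain.n_states):
            p_ref = 0.5 * min(1.0, math.exp(-(E[j + 2] - E[j + 1])))
            q_ref = 0.5 * min(1.0, math.exp(-(E[j] - E[j + 1])))
            assert math.exp(chain.log_p[j]) == pytest.approx(p_ref, rel=1e-12)
            assert math.exp(chain.log_q[j]) == pytest.approx(q_ref, rel=1e-12)

    def test_detailed_balance_ratios(self, bench_chains, bench):
        land = build_landscape(bench["a"].sequence, Direction.CIS_TO_TRANS)
        chain = bench_chains["a"]
        E = land.energies
        for j in range(chain.n_states - 1):
            lhs = chain.log_p[j] - chain.log_q[j + 1]
            assert lhs == pytest.approx(-(E[j + 2] - E[j + 1]), abs=1e-10)


class TestSplittingProbability:
    def test_flat_landscape_gamblers_ruin(self, flat_chain):
        assert splitting_probability(flat_chain) == pytest.approx(6 / 27, rel=1e-12)

    def test_monotone_in_start_point(self, bench_chains):
        for chain in bench_chains.values():
            probs = [splitting_probability(chain, start=j) for j in range(chain.n_states)]
            assert all(b >= a for a, b in zip(probs, probs[1:]))
            assert probs[0] < probs[chain.start_index] < probs[-1]

    def test_agrees_with_dense_linear_solve(self, bench_chains):
        for chain in bench_chains.values():
            dense = _dense_splitting(chain)
            assert splitting_probability(chain) == pytest.approx(
                dense[chain.start_index], abs=1e-10
            )

    def test_invariant_under_uniform_rescaling(self, bench_chains):
        chain = bench_chains["b"]
        lazy = Chain1D(
            chain.log_p + math.log(0.3), chain.log_q + math.log(0.3), chain.start_index
        )
        assert splitting_probability(lazy) == pytest.approx(
            splitting_probability(chain), rel=1e-12
        )


class TestAbsorptionDistribution:
    def test_mass_conserved_every_step(self, bench_chains):
        chain = bench_chains["a"]
        dist = absorption_time_distribution(chain, 3000)
        total = dist.survival + np.cumsum(dist.translocated + dist.rejected)
        np.testing.assert_allclose(total, 1.0, atol=1e-12)

    def test_no_absorption_before_shortest_path(self, flat_chain):
        dist = absorption_time_distribution(flat_chain, 10)
        # six hops to the rejection absorber, 21 to the translocation side
        assert dist.rejected[:5].sum() == 0.0
        assert dist.rejected[5] > 0.0
        assert dist.translocated[:10].sum() == 0.0

    def test_total_mass_converges_to_splitting(self, flat_chain):
        dist = absorption_time_distribution(flat_chain, 6000)
        assert dist.survival[-1] < 1e-10
        assert dist.p_translocated == pytest.approx(
            splitting_probability(flat_chain), abs=1e-9
        )


class TestClassification:
    def test_three_way_probabilities_sum_to_one(self, bench):
        for record in bench.values():
            land = build_landscape(record.sequence, Direction.CIS_TO_TRANS)
            cls = classify_exact(land, 2000)
            assert cls.p_translocated + cls.p_rejected + cls.p_trapped == pytest.approx(
                1.0, abs=1e-10
            )

    def test_long_waiting_time_recovers_splitting(self, flat_chain, flat_profile, bench):
        seq = ChargeSequence((1,) * 20, "flat")
        land = build_landscape(seq, Direction.CIS_TO_TRANS, flat_profile)
        cls = classify_exact(land, 8000)
        assert cls.p_trapped < 1e-12
        assert cls.p_translocated == pytest.approx(6 / 27, abs=1e-10)

    def test_no_translocation_mass_gives_nan_moments(self):
        # translocation needs 21 net forward hops; within 20 attempts the
        # translocated mass is identically zero and its moments undefined
        seq = ChargeSequence((-1,) * 20, "antag")
        land = build_landscape(seq, Direction.CIS_TO_TRANS)
        cls = classify_exact(land, 20)
        assert cls.p_translocated == 0.0
        assert math.isnan(cls.mean_translocation_time)


class TestFirstPassageMoments:
    def test_flat_landscape_classic_mean(self, flat_chain):
        # symmetric walk between absorbers 6 and 21 steps away: mean 6*21
        fp = mean_first_passage(flat_chain)
        assert fp.mean == pytest.approx(126.0, rel=1e-10)

    def test_decomposition_identity(self, bench_chains):
        for chain in bench_chains.values():
            fp = mean_first_passage(chain)
            recomposed = (
                fp.p_translocated * fp.mean_translocated
                + (1 - fp.p_translocated) * fp.mean_rejected
            )
            assert recomposed == pytest.approx(fp.mean, rel=1e-8)

    def test_agrees_with_distribution_first_moment(self, flat_chain):
        dist = absorption_time_distribution(flat_chain, 8000)
        assert dist.survival[-1] < 1e-12
        mass = dist.translocated + dist.rejected
        mean_from_dist = float((dist.t * mass).sum())
        fp = mean_first_passage(flat_chain)
        assert fp.mean == pytest.approx(mean_from_dist, rel=1e-9)
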