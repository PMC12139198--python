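"""Independent oracles used by unit and acceptance tests.

These deliberately avoid the grid/interpolation code path of the library:
the stopping-problem oracles work on exact posterior means by recursion over
the outcome tree (and, for the tiniest instance, by literal enumeration of
every stopping policy), and the value-of-information oracles are plain
Monte Carlo over the preposterior distribution.
"""

import itertools
import math

import numpy as np

import valueseq as vs


def mc_decision_value(mu: float, s: float, econ, n_draws: int, rng):
    """Monte Carlo preposterior gain: E[max(P*W - C, 0)] - max(P*mu - C, 0)
    for W ~ N(mu, s^2).  Returns (estimate, standard error)."""
    draws = rng.normal(mu, s, n_draws)
    vals = np.maximum(econ.population_size * draws - econ.switching_cost, 0.0)
    base = max(econ.population_size * mu - econ.switching_cost, 0.0)
    return float(vals.mean() - base), float(vals.std(ddof=1) / math.sqrt(n_draws))


def tree_value(mu: float, n: int, prior, econ, gh_nodes: int) -> float:
    """Optimal-stopping value by exact recursion over the discretised
    outcome tree (no mu grid, no interpolation)."""
    n0, sigma = prior.n_eff, prior.sigma
    N = econ.max_pairs - econ.delay_pairs
    stop = vs.stop_value(mu, n0 + n, econ.delay_pairs, econ, sigma)
    if n == N:
        return stop
    x, w = np.polynomial.hermite.hermgauss(gh_nodes)
    w = w / math.sqrt(math.pi)
    s1 = sigma * math.sqrt(1.0 / ((n0 + n) * (n0 + n + 1)))
    cont = -econ.sampling_cost_per_pair + sum(
        wi * tree_value(mu + math.sqrt(2.0) * s1 * xi, n + 1, prior, econ, gh_nodes)
        for xi, wi in zip(x, w)
    )
    return max(stop, cont)


def enumerate_policies_value(mu0: float, prior, econ, gh_nodes: int) -> float:
    """Exhaustive maximum over every stopping policy for a 2-stage problem.

    Decision points are n = 0 and the ``gh_nodes`` posterior means reachable
    at n = 1; n = 2 is a forced stop.  Every (1 + gh_nodes)-bit action
    assignment is evaluated by averaging over the full outcome tree.
    """
    n0, sigma = prior.n_eff, prior.sigma
    delta, c = econ.delay_pairs, econ.sampling_cost_per_pair
    assert econ.max_pairs - delta == 2
    x, w = np.polynomial.hermite.hermgauss(gh_nodes)
    w = w / math.sqrt(math.pi)
    s1_0 = sigma * math.sqrt(1.0 / (n0 * (n0 + 1)))
    s1_1 = sigma * math.sqrt(1.0 / ((n0 + 1) * (n0 + 2)))
    mu1 = [mu0 + math.sqrt(2.0) * s1_0 * xi for xi in x]

    best = -math.inf
    for actions in itertools.product([0, 1], repeat=1 + gh_nodes):
        if actions[0] == 0:
            value = vs.stop_value(mu0, n0, delta, econ, sigma)
        else:
            value = -c
            for j, (m1, wj) in enumerate(zip(mu1, w)):
                if actions[1 + j] == 0:
                    value += wj * vs.stop_value(m1, n0 + 1, delta, econ, sigma)
                else:
                    inner = -c + sum(
                        wk * vs.stop_value(m1 + math.sqrt(2.0) * s1_1 * xk, n0 + 2, delta, econ, sigma)
                        for xk, wk in zip(x, w)
                    )
                    value += wj * inner
        best = max(best, value)
    return best


def realised_net_value(path, econ) -> float:
    """Realised value of one rolled-out path on the DP's accounting:
    terminal decision value minus Stage II sampling costs (Stage I cost
    c * delay and the fixed cost are sunk and excluded, as in the solver)."""
    gain = econ.population_size * max(path.final_mu - econ.adoption_threshold, 0.0)
    return gain - econ.sampling_cost_per_pair * path.n_stop_observed
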