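import dataclasses
import math

import numpy as np
import pytest

import valueseq as vs


def hand_boundary(prior, econ, upper=None, lower=None):
    """Boundary with hand-set thresholds (defaults: effectively never stop
    before the forced final stage)."""
    N = econ.max_pairs - econ.delay_pairs
    up = [1e12] * N + [None]
    lo = [-1e12] * N + [None]
    if upper:
        for n, v in upper.items():
            up[n] = v
    if lower:
        for n, v in lower.items():
            lo[n] = v
    return vs.Boundary(
        n_grid=np.arange(N + 1),
        lower=tuple(lo),
        upper=tuple(up),
        value0=0.0,
        prior=prior,
        econ=econ,
        grid=vs.GridSpec(-1e12, 1e12),
    )


@pytest.fixture(scope="module")
def hero_design():
    econ = vs.EconDesign(
        wtp=30_000.0, population_size=11_000.0, sampling_cost_per_pair=1500.0,
        delay_pairs=74, max_pairs=124, fixed_trial_cost=650_000.0,
        interim_every_k=10, min_pairs_first_interim=20,
    )
    prior = vs.make_prior(0.0, 2.0, 15_000.0)
    return econ, prior


class TestMonitor:
    def test_path_inside_region_runs_to_maximum(self, hero_design):
        econ, prior = hero_design
        b = hand_boundary(prior, econ)
        diffs = np.zeros(124)
        decision, path = vs.monitor(b, vs.PairSeries(diffs), prior, econ)
        assert decision == "stage_III_complete"
        assert path.n_stop_observed == 50  # forced stop at T - delay
        assert path.total_pairs_recruited == 124

    def test_crossing_between_interims_stops_at_later_interim(self, hero_design):
        """A path exiting the region between the 30- and 40-pair looks is
        caught at 40; with 74 pipeline pairs the trial totals 114 pairs."""
        econ, prior = hero_design
        b = hand_boundary(prior, econ, upper={40: 500.0, 50: 500.0})
        diffs = np.full(124, 1000.0)  # posterior mean rises towards 1000
        decision, path = vs.monitor(b, vs.PairSeries(diffs), prior, econ)
        assert decision == "stage_III_complete"
        assert path.n_stop_observed == 40
        assert path.total_pairs_recruited == 114
        evaluated = [n for n, _ in path.interim_states]
        assert evaluated == [20, 30, 40]

    def test_first_scheduled_interim_skipped_for_sparsity(self, hero_design):
        econ, prior = hero_design
        b = hand_boundary(prior, econ)
        _, path = vs.monitor(b, vs.PairSeries(np.zeros(30)), prior, econ)
        assert (10, "data sparsity") in path.skipped_interims

    def test_empty_continuation_stops_at_first_interim(self, hero_design):
        econ, prior = hero_design
        N = econ.max_pairs - econ.delay_pairs
        b = vs.Boundary(
            n_grid=np.arange(N + 1), lower=(None,) * (N + 1), upper=(None,) * (N + 1),
            value0=0.0, prior=prior, econ=econ, grid=vs.GridSpec(-1e12, 1e12),
        )
        decision, path = vs.monitor(b, vs.PairSeries(np.zeros(124)), prior, econ)
        assert decision == "stage_III_complete"
        assert path.n_stop_observed == 20
        assert path.total_pairs_recruited == 94

    def test_partial_series_continues_then_stops(self, hero_design):
        econ, prior = hero_design
        b = hand_boundary(prior, econ, upper={40: 500.0})
        decision, _ = vs.monitor(b, vs.PairSeries(np.full(25, 1000.0)), prior, econ)
        assert decision == "continue"
        decision, path = vs.monitor(b, vs.PairSeries(np.full(45, 1000.0)), prior, econ)
        assert decision == "stop_recruitment"
        assert path.total_pairs_recruited == 114
        assert math.isnan(path.final_mu)

    def test_overrun_series_rejected(self, hero_design):
        econ, prior = hero_design
        b = hand_boundary(prior, econ)
        with pytest.raises(vs.ValueSeqError, match="maximum"):
            vs.monitor(b, vs.PairSeries(np.zeros(125)), prior, econ)

    def test_mismatched_design_rejected(self, hero_design):
        econ, prior = hero_design
        b = hand_boundary(prior, econ)
        other = dataclasses.replace(econ, population_size=99.0)
        with pytest.raises(vs.ValueSeqError, match="different prior/design"):
            vs.monitor(b, vs.PairSeries(np.zeros(10)), prior, other)


class TestSimulatePaths:
    def test_sample_size_identity_on_every_path(self, std_prior, std_econ, std_boundary):
        paths = vs.simulate_paths(
            0.0, std_prior.sigma, std_prior, std_boundary, std_econ, n_reps=200, seed=3
        )
        for p in paths:
            assert p.total_pairs_recruited == min(
                p.n_stop_observed + std_econ.delay_pairs, std_econ.max_pairs
            )
            assert p.trial_cost == pytest.approx(
                std_econ.sampling_cost_per_pair * p.total_pairs_recruited
                + std_econ.fixed_trial_cost
            )

    def test_seed_reproducibility(self, std_prior, std_econ, std_boundary):
        a = vs.simulate_paths(100.0, std_prior.sigma, std_prior, std_boundary, std_econ, 50, seed=9)
        b = vs.simulate_paths(100.0, std_prior.sigma, std_prior, std_boundary, std_econ, 50, seed=9)
        assert a == b
        c = vs.simulate_paths(100.0, std_prior.sigma, std_prior, std_boundary, std_econ, 50, seed=10)
        assert a != c

    def test_noiseless_favourable_truth_always_adopts(self, std_prior, std_econ, std_boundary):
        paths = vs.simulate_paths(
            5000.0, 1e-6, std_prior, std_boundary, std_econ, n_reps=50, seed=1
        )
        assert all(p.adopted == "A" for p in paths)


class TestBootstrapPaths:
    def test_degenerate_resampling_gives_identical_paths(self, hero_design):
        econ, prior = hero_design
        b = hand_boundary(prior, econ, upper={n: 400.0 for n in (20, 30, 40, 50)})
        records = []
        for i in range(10):  # every pair's INMB diff is exactly +500, above the bound
            records.append(vs.PatientRecord(f"{i}", "A", 0.5, 0.0))
            records.append(vs.PatientRecord(f"{i}", "B", 0.5, 500.0))
        paths = vs.bootstrap_paths(records, prior, b, econ, n_reps=20, seed=4)
        assert len({p.n_stop_observed for p in paths}) == 1
        assert paths[0].n_stop_observed == 20  # first permissible interim
        assert all(p == paths[0] for p in paths)

    def test_single_replicate_statistics_equal_that_path(self, hero_design):
        econ, prior = hero_design
        b = hand_boundary(prior, econ)
        rng = np.random.default_rng(0)
        records = []
        for i in range(30):
            records.append(vs.PatientRecord(f"{i}", "A", rng.uniform(0, 1), rng.uniform(0, 2000)))
            records.append(vs.PatientRecord(f"{i}", "B", rng.uniform(0, 1), rng.uniform(0, 2000)))
        paths = vs.bootstrap_paths(records, prior, b, econ, n_reps=1, seed=5)
        oc = vs.operating_characteristics(paths, econ)
        assert oc.expected_pairs == paths[0].total_pairs_recruited
        assert oc.expected_net_benefit == pytest.approx(
            econ.population_size * max(paths[0].final_mu, 0.0) - paths[0].trial_cost
        )

    def test_insufficient_pairs_rejected(self, hero_design):
        econ, prior = hero_design
        b = hand_boundary(prior, econ)
        records = [
            vs.PatientRecord("0", "A", 0.5, 0.0),
            vs.PatientRecord("0", "B", 0.5, 0.0),
        ]
        with pytest.raises(vs.InsufficientDataError):
            vs.bootstrap_paths(records, prior, b, econ, n_reps=5, seed=0)


def make_path(total, final_mu, n_stop, econ):
    return vs.TrialPath(
        interim_states=(), n_stop_observed=n_stop, total_pairs_recruited=total,
        final_mu=final_mu, adopted="A" if final_mu > econ.adoption_threshold else "B",
        trial_cost=econ.sampling_cost_per_pair * total + econ.fixed_trial_cost,
    )


class TestOperatingCharacteristics:
    def test_hand_computed_fixture(self, std_econ):
        e = std_econ
        paths = [make_path(100, mu, 70, e) for mu in [-500, -100, 0, 200, 800, 1200, -300, 50, 400, -900]]
        oc = vs.operating_characteristics(paths, e)
        assert oc.expected_pairs == 100.0
        assert oc.expected_cost == pytest.approx(100 * 1000.0)
        assert oc.prob_cost_effective == pytest.approx(5 / 10)
        mus = np.array([-500, -100, 0, 200, 800, 1200, -300, 50, 400, -900], dtype=float)
        expected_nb = np.mean(e.population_size * np.maximum(mus, 0) - 100 * 1000.0)
        assert oc.expected_net_benefit == pytest.approx(expected_nb)
        assert oc.expected_cost == pytest.approx(
            e.sampling_cost_per_pair * oc.expected_pairs + e.fixed_trial_cost
        )

    def test_opposite_signs_give_half(self, std_econ):
        paths = [make_path(50, -10.0, 20, std_econ), make_path(50, 10.0, 20, std_econ)]
        assert vs.operating_characteristics(paths, std_econ).prob_cost_effective == 0.5

    def test_order_invariance_and_degenerate_se(self, std_econ):
        paths = [make_path(60, 100.0, 30, std_econ)] * 4
        oc = vs.operating_characteristics(paths, std_econ)
        assert oc.mc_se["expected_pairs"] == 0.0
        shuffled = vs.operating_characteristics(paths[::-1], std_econ)
        assert oc.expected_net_benefit == shuffled.expected_net_benefit

    def test_empty_rejected(self, std_econ):
        with pytest.raises(vs.InsufficientDataError):
            vs.operating_characteristics([], std_econ)

    def test_mc_se_scales_with_replicates(self, std_prior, std_econ, std_boundary):
        p1 = vs.simulate_paths(0.0, std_prior.sigma, std_prior, std_boundary, std_econ, 400, seed=21)
        p2 = vs.simulate_paths(0.0, std_prior.sigma, std_prior, std_boundary, std_econ, 800, seed=21)
        se1 = vs.operating_characteristics(p1, std_econ).mc_se["expected_net_benefit"]
        se2 = vs.operating_characteristics(p2, std_econ).mc_se["expected_net_benefit"]
        assert 1.1 < se1 / se2 < 1.8  # ~sqrt(2)


class TestFrequentistOc:
    def test_symmetric_null_and_monotone_power(self, std_prior, std_econ, std_boundary):
        grid = [-3000.0, 0.0, 3000.0]
        table = vs.frequentist_oc(
            grid, std_prior.sigma, std_prior, std_boundary, std_econ, n_reps=400, seed=13
        )
        null = table[table.true_mean == 0.0].iloc[0]
        assert abs(null.prob_adopt_A - 0.5) < 3 * null.prob_adopt_A_se + 1e-12
        p = table.prob_adopt_A.to_numpy()
        se = table.prob_adopt_A_se.to_numpy()
        assert np.all(np.diff(p) > -3 * np.sqrt(se[:-1] ** 2 + se[1:] ** 2))

    def test_near_zero_noise_power_step(self, std_prior, std_econ, std_boundary):
        table = vs.frequentist_oc(
            [-2000.0, 2000.0], 1e-6, std_prior, std_boundary, std_econ, n_reps=20, seed=2
        )
        assert table.prob_adopt_A.tolist() == [0.0, 1.0]

    def test_empty_grid_rejected(self, std_prior, std_econ, std_boundary):
        with pytest.raises(vs.InvalidParameterError):
            vs.frequentist_oc([], std_prior.sigma, std_prior, std_boundary, std_econ, 10, 0)
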