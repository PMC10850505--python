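import numpy as np
import pytest
from scipy import stats

from saxser.amd import AmdParameters
from saxser.saxs import chi2, compute_profile, ensemble_profile, rg_from_coords
from saxser.synthetic import (
    GenerationError,
    NoiseModel,
    StericRejection,
    ToyEnergyParams,
    ToySampler,
    TwoDomainSpec,
    bound_reference_state,
    linker_state_for_rg,
    make_peak_list_pair,
    make_pool,
    make_two_domain_conformer,
    simulate_saxs_experiment,
    toy_sampler,
)


class TestTwoDomainConformer:
    def test_determinism(self, small_spec_apo):
        state = np.zeros(2 * small_spec_apo.n_link)
        a = make_two_domain_conformer(small_spec_apo, state)
        b = make_two_domain_conformer(small_spec_apo, state)
        np.testing.assert_array_equal(a.points, b.points)

    def test_extension_maximizes_separation(self, small_spec_apo):
        def centroid_sep(bend):
            state = np.zeros(2 * small_spec_apo.n_link)
            state[::2] = bend
            m = make_two_domain_conformer(small_spec_apo, state)
            c1 = m.points[: small_spec_apo.n1].mean(axis=0)
            c2 = m.points[-small_spec_apo.n2 :].mean(axis=0)
            return np.linalg.norm(c2 - c1)

        seps = [centroid_sep(b) for b in (0.0, 0.2, 0.4, 0.6)]
        assert seps[0] == max(seps)
        assert all(np.diff(seps) < 0)

    def test_point_count_and_labels(self, small_spec_apo):
        m = make_two_domain_conformer(small_spec_apo, np.zeros(2 * small_spec_apo.n_link))
        assert len(m) == small_spec_apo.n_total
        assert m.labels[0][1] == 56

    def test_steric_rejection(self):
        # tightly crumpled linker states fold the domains into overlap;
        # a seeded search over random states must hit the rejection branch
        spec = TwoDomainSpec(n1=30, n_link=8, n2=30, seed=1)
        rng = np.random.default_rng(0)
        rejected = None
        for _ in range(3000):
            state = np.empty(2 * spec.n_link)
            state[::2] = rng.uniform(0, np.pi * 0.9, spec.n_link)
            state[1::2] = rng.uniform(-np.pi, np.pi, spec.n_link)
            try:
                make_two_domain_conformer(spec, state)
            except StericRejection:
                rejected = state
                break
        assert rejected is not None
        with pytest.raises(StericRejection):  # deterministic on replay
            make_two_domain_conformer(spec, rejected)

    def test_bound_more_compact_than_apo(self):
        apo = TwoDomainSpec(mode="apo", seed=11)
        bound = TwoDomainSpec(mode="bound", seed=11)
        rg_apo = [rg_from_coords(m) for m in make_pool(apo, 500, seed=21).members]
        rg_bound = [rg_from_coords(m) for m in make_pool(bound, 500, seed=22).members]
        pooled_sd = np.sqrt((np.var(rg_apo) + np.var(rg_bound)) / 2)
        assert np.mean(rg_apo) - np.mean(rg_bound) > 3 * pooled_sd
        assert np.std(rg_apo) > np.std(rg_bound)


class TestLinkerStateForRg:
    def test_hits_target(self, small_spec_bound):
        state = linker_state_for_rg(small_spec_bound, 12.0, tol=0.05)
        m = make_two_domain_conformer(small_spec_bound, state)
        assert rg_from_coords(m) == pytest.approx(12.0, abs=0.06)

    def test_unreachable_target(self, small_spec_bound):
        with pytest.raises(GenerationError, match="exceeds"):
            linker_state_for_rg(small_spec_bound, 1000.0)


class TestMakePool:
    def test_single_and_seed_determinism(self, small_spec_apo):
        one = make_pool(small_spec_apo, 1, seed=5)
        assert len(one) == 1
        a = make_pool(small_spec_apo, 4, seed=6)
        b = make_pool(small_spec_apo, 4, seed=6)
        for ma, mb in zip(a.members, b.members):
            np.testing.assert_array_equal(ma.points, mb.points)

    def test_different_seeds_differ(self, small_spec_apo):
        a = make_pool(small_spec_apo, 1, seed=1).members[0]
        b = make_pool(small_spec_apo, 1, seed=2).members[0]
        assert not np.allclose(a.points, b.points)


class TestSimulateSaxsExperiment:
    def test_sigma_is_generating_sigma(self, small_spec_bound, coarse_q):
        truth = make_pool(small_spec_bound, 3, seed=31).members
        curve = simulate_saxs_experiment(truth, None, coarse_q, NoiseModel(seed=41))
        ideal = ensemble_profile([compute_profile(m, coarse_q) for m in truth])
        np.testing.assert_allclose(curve.sigma, 0.02 * ideal.I)

    def test_noise_free_limit(self, small_spec_bound, coarse_q):
        truth = make_pool(small_spec_bound, 3, seed=31).members
        tiny = simulate_saxs_experiment(
            truth, None, coarse_q, NoiseModel(relative_sd=1e-12, seed=41)
        )
        ideal = ensemble_profile([compute_profile(m, coarse_q) for m in truth])
        fit = chi2(ideal, tiny, mu=1.0)
        np.testing.assert_allclose(tiny.I, ideal.I, rtol=1e-9)

    def test_chi2_calibration(self, small_spec_bound, coarse_q):
        truth = make_pool(small_spec_bound, 3, seed=31).members
        ideal = ensemble_profile([compute_profile(m, coarse_q) for m in truth])
        values = []
        for seed in range(100):
            curve = simulate_saxs_experiment(truth, None, coarse_q, NoiseModel(seed=seed))
            values.append(chi2(ideal, curve, mu=1.0).chi2)
        assert 0.85 < np.mean(values) < 1.15


class TestToySampler:
    def test_equal_seeds_identical_bursts(self, small_spec_bound):
        sampler = toy_sampler(small_spec_bound)
        start = make_two_domain_conformer(
            small_spec_bound, bound_reference_state(small_spec_bound)
        )
        a = sampler.burst(start, 40, seed=9, n_snapshots=4)
        b = sampler.burst(start, 40, seed=9, n_snapshots=4)
        assert len(a) == len(b) == 4
        for ma, mb in zip(a, b):
            np.testing.assert_array_equal(ma.points, mb.points)

    def test_point_count_preserved(self, small_spec_bound):
        sampler = toy_sampler(small_spec_bound)
        start = make_two_domain_conformer(
            small_spec_bound, bound_reference_state(small_spec_bound)
        )
        for snap in sampler.burst(start, 30, seed=2, n_snapshots=3):
            assert len(snap) == len(start)

    def test_zero_temperature_descends(self, small_spec_bound):
        params = ToyEnergyParams(
            reference_states=[bound_reference_state(small_spec_bound)], temperature=1e-9
        )
        sampler = ToySampler(small_spec_bound, params)
        start_state = bound_reference_state(small_spec_bound) + 0.3
        start_state[::2] = np.clip(start_state[::2], 0, np.pi * 0.9)
        start = make_two_domain_conformer(small_spec_bound, start_state)
        snaps = sampler.burst(start, 60, seed=3, n_snapshots=6)
        energies = [sampler.energy(np.asarray(s.linker_state)) for s in snaps]
        assert all(e2 <= e1 + 1e-9 for e1, e2 in zip(energies, energies[1:]))
        assert energies[-1] < sampler.energy(start_state)

    def test_boost_broadens_exploration(self, small_spec_bound):
        ref = bound_reference_state(small_spec_bound)
        start = make_two_domain_conformer(small_spec_bound, ref)
        plain_sd, boosted_sd = [], []
        # thresholds above every visited energy: the boost is always on and
        # compresses the well, so the walk explores a wider Rg range
        boost = AmdParameters(e_p=80.0, alpha_p=8.0, e_d=80.0, alpha_d=8.0)
        for seed in range(5):
            plain = ToySampler(small_spec_bound, ToyEnergyParams(reference_states=[ref]))
            snaps = plain.burst(start, 200, seed=seed, n_snapshots=100)
            plain_sd.append(np.var([rg_from_coords(s) for s in snaps], ddof=1))
            hot = ToySampler(
                small_spec_bound, ToyEnergyParams(reference_states=[ref], boost=boost)
            )
            snaps = hot.burst(start, 200, seed=seed, n_snapshots=100)
            boosted_sd.append(np.var([rg_from_coords(s) for s in snaps], ddof=1))
        # pooled F-test on the variance ratio
        f = np.mean(boosted_sd) / np.mean(plain_sd)
        df = 5 * (100 - 1)
        p = stats.f.sf(f, df, df)
        assert f > 1.0
        assert p < 0.05

    def test_conformer_without_metadata_rejected(self, small_spec_bound):
        from saxser.model_io import ConformerModel

        sampler = toy_sampler(small_spec_bound)
        bare = ConformerModel(id="bare", points=np.random.default_rng(0).normal(size=(10, 3)))
        with pytest.raises(GenerationError, match="metadata"):
            sampler.burst(bare, 10, seed=1)


class TestMakePeakListPair:
    def test_no_plant_no_vanish_zero_csp(self):
        from saxser.binding import csp_compute

        free, bound = make_peak_list_pair(50, [], [], seed=1)
        records, missing = csp_compute(free, bound)
        assert all(r.csp == 0.0 for r in records)
        assert missing["missing_in_bound"] == []

    def test_vanish_reported_missing(self):
        from saxser.binding import csp_compute

        free, bound = make_peak_list_pair(50, [], [17, 23], seed=2, prolines=[5])
        _, missing = csp_compute(free, bound)
        assert missing["missing_in_bound"] == [17, 23]

    def test_prolines_absent_from_both(self):
        free, bound = make_peak_list_pair(30, [], [], seed=3, prolines=[4, 9])
        assert {4, 9} & free.residues() == set()
        assert {4, 9} & bound.residues() == set()

    def test_overlap_config_error(self):
        with pytest.raises(GenerationError, match="overlap"):
            make_peak_list_pair(30, [(7, 0.1, 0.5)], [7], seed=4)

    def test_deterministic(self):
        a = make_peak_list_pair(40, [(10, 0.2, 1.0)], [20], seed=9, prolines=[3])
        b = make_peak_list_pair(40, [(10, 0.2, 1.0)], [20], seed=9, prolines=[3])
        assert a[0].entries == b[0].entries and a[1].entries == b[1].entries
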