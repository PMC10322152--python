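import numpy as np
import pytest

from statecoev import free_energy as fe, synthetic
from statecoev.errors import (AlignmentGapError, BinningError, DataError,
                              InsufficientDataError, OrderingError)
from statecoev.free_energy import BiasedEnsemble, BinGrid, R_GAS

RT = R_GAS * 298.0


def _ensemble(xi, bias=None, walker=None, temperature=298.0):
    xi = np.asarray(xi, dtype=float)
    n = xi.size
    if walker is None:
        walker = np.zeros(n, dtype=int)
    time = np.concatenate([np.arange((walker == w).sum())
                           for w in np.unique(walker)]).astype(float)
    order = np.argsort(walker, kind="stable")
    return BiasedEnsemble(time=time, walker=np.sort(walker), xi=xi[order],
                          bias=np.zeros(n) if bias is None else np.asarray(bias)[order],
                          temperature=temperature)


class TestFrameWeights:
    def test_zero_bias_single_bin_uniform(self):
        ens = _ensemble(np.full(10, 0.5))
        grid = BinGrid(0.0, 1.0, 1)
        w = fe.frame_weights(ens, grid)
        assert np.allclose(w, 1.0 / 10)

    def test_bias_ratio_between_bins(self):
        # equal occupancy; bin 2 biased by RT ln 2 -> per-frame weights 2:1
        xi = np.array([0.25] * 4 + [0.75] * 4)
        bias = np.array([RT * np.log(2.0)] * 4 + [0.0] * 4)
        ens = _ensemble(xi, bias)
        w = fe.frame_weights(ens, BinGrid(0.0, 1.0, 2))
        ratio = w[ens.xi > 0.5].mean() / w[ens.xi < 0.5].mean()
        assert ratio == pytest.approx(2.0, rel=1e-9)

    def test_frame_outside_grid_rejected(self):
        ens = _ensemble([0.5, 1.5])
        with pytest.raises(BinningError):
            fe.frame_weights(ens, BinGrid(0.0, 1.0, 4))

    def test_reweighting_recovers_boltzmann(self):
        # frames drawn under a known bias reweight to the unbiased surface
        F = synthetic.double_well(10.0)
        ens = synthetic.make_biased_trajectory(F, F, n_frames=40000,
                                               n_walkers=4, seed=5)
        grid = BinGrid(-1.8, 1.8, 80)
        w = fe.frame_weights(ens, grid)
        prof = fe.project_free_energy(ens, w, ens.xi, grid)
        centers = prof.centers
        ref = F(centers) - F(centers)[prof.occupied].min()
        sel = prof.occupied & (ref < 6.0)
        assert np.nanmax(np.abs(prof.E[sel] - ref[sel])) < 0.6


class TestProjectFreeEnergy:
    def test_uniform_weights_reduce_to_histogram(self, rng):
        coord = rng.uniform(0, 1, 2000)
        ens = _ensemble(coord)
        grid = BinGrid(0.0, 1.0, 5)
        w = np.ones(2000)
        prof = fe.project_free_energy(ens, w, coord, grid)
        counts = np.histogram(coord, bins=grid.edges)[0]
        expected = -RT * np.log(counts / 2000)
        expected -= expected.min()
        assert np.allclose(prof.E, expected, atol=1e-9)

    def test_single_bin_gauge_zero(self):
        ens = _ensemble(np.full(50, 0.3))
        prof = fe.project_free_energy(ens, np.ones(50), ens.xi,
                                      BinGrid(0.0, 1.0, 1))
        assert prof.E[0] == pytest.approx(0.0)

    def test_empty_bins_flagged_not_raised(self):
        ens = _ensemble(np.concatenate([np.full(10, 0.1), np.full(10, 0.9)]))
        prof = fe.project_free_energy(ens, np.ones(20), ens.xi,
                                      BinGrid(0.0, 1.0, 10))
        assert np.isnan(prof.E[5])
        assert prof.occupied.sum() == 2

    def test_gauge_invariant_under_frame_duplication(self, rng):
        coord = rng.uniform(0, 1, 500)
        grid = BinGrid(0.0, 1.0, 8)
        e1 = fe.project_free_energy(_ensemble(coord), np.ones(500), coord, grid)
        dup = np.concatenate([coord, coord])
        e2 = fe.project_free_energy(_ensemble(dup), np.ones(1000), dup, grid)
        assert np.allclose(e1.E[e1.occupied], e2.E[e2.occupied], atol=1e-9)


class TestAlignProfiles:
    def _profile(self, rng, n=20, label="p"):
        E = rng.uniform(0, 8, n)
        E -= E.min()
        return fe.FreeEnergyProfile(centers=np.linspace(0, 1, n), E=E,
                                    se=np.full(n, 0.5),
                                    n_eff=np.full(n, 100.0), label=label)

    def test_shifted_copy_offset_recovered(self, rng):
        p = self._profile(rng)
        shifted = p.shifted(7.0)
        _combined, offsets = fe.align_profiles([p, shifted])
        assert offsets[0] == 0.0
        assert offsets[1] == pytest.approx(-7.0, abs=1e-9)

    def test_single_profile_unchanged(self, rng):
        p = self._profile(rng)
        combined, offsets = fe.align_profiles([p])
        assert offsets == [0.0]
        assert np.allclose(combined.E, p.E)

    def test_translation_equivariance(self, rng):
        p1, p2, p3 = (self._profile(rng, label=s) for s in "abc")
        _c, base = fe.align_profiles([p1, p2, p3])
        _c2, moved = fe.align_profiles([p1, p2.shifted(3.0), p3])
        assert moved[1] == pytest.approx(base[1] - 3.0, abs=1e-9)
        assert moved[2] == pytest.approx(base[2], abs=1e-9)

    def test_disconnected_overlap_rejected(self, rng):
        n = 20
        centers = np.linspace(0, 1, n)
        E1 = np.where(np.arange(n) < 10, 1.0, np.nan)
        E2 = np.where(np.arange(n) >= 12, 1.0, np.nan)
        mk = lambda E: fe.FreeEnergyProfile(centers=centers, E=E,
                                            se=np.full(n, 0.5),
                                            n_eff=np.full(n, 10.0))
        with pytest.raises(AlignmentGapError):
            fe.align_profiles([mk(E1), mk(E2)])

    def test_combination_reduces_noise(self, rng):
        # three noisy copies of one surface: the combined profile tracks the
        # truth better than the worst individual segment
        centers = np.linspace(0, 1, 30)
        truth = 8.0 * (centers - 0.5) ** 2
        profiles = []
        for k in range(3):
            E = truth + rng.normal(0, 0.4, 30) + k * 2.0
            E -= E.min()
            profiles.append(fe.FreeEnergyProfile(
                centers=centers, E=E, se=np.full(30, 0.4),
                n_eff=np.full(30, 50.0), label=str(k)))
        combined, _ = fe.align_profiles(profiles)
        def rms(E):
            d = E - truth
            d -= np.nanmean(d)
            return np.sqrt(np.nanmean(d ** 2))
        assert rms(combined.E) < max(rms(p.E) for p in profiles)


class TestTransitionImbalance:
    def test_alternating_transitions_balance(self):
        # closed loop: equal numbers of up and down crossings
        xi = np.concatenate([np.tile([0.25, 0.75], 50), [0.25]])
        ens = _ensemble(xi)
        err = fe.transition_imbalance_error(ens, BinGrid(0.0, 1.0, 2))
        assert np.allclose(err, 0.0, atol=1e-9)

    def test_two_to_one_imbalance(self):
        # each walker crosses up twice and down once; pooled counts give
        # N_ij = 2 N_ji and an edge error of ~ RT ln 2 ~ 1.7 kJ/mol at 298 K
        n_walkers = 100
        xi = np.tile([0.25, 0.75, 0.25, 0.75], n_walkers)
        walker = np.repeat(np.arange(n_walkers), 4)
        ens = _ensemble(xi, walker=walker)
        err = fe.transition_imbalance_error(ens, BinGrid(0.0, 1.0, 2))
        expected = RT * np.log(2.0)
        assert abs((err.max() - err.min()) - expected) < 0.05

    def test_single_frame_walker_rejected(self):
        ens = _ensemble([0.5])
        with pytest.raises(InsufficientDataError):
            fe.transition_imbalance_error(ens, BinGrid(0.0, 1.0, 2))

    def test_error_shrinks_with_length(self):
        flat = lambda x: np.zeros_like(np.asarray(x, dtype=float))
        def mean_err(n, seed):
            ens = synthetic.make_biased_trajectory(flat, flat, n_frames=n,
                                                   n_walkers=2, seed=seed)
            return fe.transition_imbalance_error(
                ens, BinGrid(-1.8, 1.8, 20)).mean()
        short = np.mean([mean_err(8000, s) for s in range(3)])
        long = np.mean([mean_err(32000, 10 + s) for s in range(3)])
        assert long < short


class TestWalkerOverlap:
    def test_single_walker(self):
        ens = _ensemble(np.linspace(0.05, 0.95, 50))
        O = fe.walker_overlap(ens, BinGrid(0.0, 1.0, 5))
        assert np.all(O == 1)

    def test_identical_walkers_full_overlap(self):
        xi = np.tile(np.linspace(0.05, 0.95, 25), 4)
        walker = np.repeat(np.arange(4), 25)
        ens = _ensemble(xi, walker=walker)
        O = fe.walker_overlap(ens, BinGrid(0.0, 1.0, 5))
        assert np.all(O == 4)

    def test_disjoint_halves_tally(self):
        xi = np.concatenate([np.linspace(0.02, 0.48, 25),
                             np.linspace(0.02, 0.48, 25),
                             np.linspace(0.52, 0.98, 25),
                             np.linspace(0.52, 0.98, 25)])
        walker = np.repeat(np.arange(4), 25)
        ens = _ensemble(xi, walker=walker)
        O = fe.walker_overlap(ens, BinGrid(0.0, 1.0, 4))
        assert list(O) == [2, 2, 2, 2]

    def test_raw_threshold_variant(self):
        xi = np.tile(np.linspace(0.05, 0.95, 25), 2)
        walker = np.repeat(np.arange(2), 25)
        ens = _ensemble(xi, walker=walker)
        O = fe.walker_overlap(ens, BinGrid(0.0, 1.0, 2),
                              normalize_by_mean=False, threshold=0.4)
        assert np.all(O == 2)


class TestConvergence:
    def _prof(self, E):
        E = np.asarray(E, dtype=float)
        return fe.FreeEnergyProfile(centers=np.arange(E.size, dtype=float),
                                    E=E, se=np.full(E.size, 0.1),
                                    n_eff=np.full(E.size, 10.0))

    def test_identical_snapshots_pass(self):
        p = self._prof([0, 1, 2, 3])
        report = fe.convergence_check([p, p, p])
        assert report["converged"]
        assert report["norm_series"] == [0.0, 0.0]

    def test_drifting_snapshots_fail(self):
        snaps = [self._prof(np.arange(4) + k * 1.0) for k in range(3)]
        report = fe.convergence_check(snaps, dF_tol=0.5)
        assert not report["dF_converged"]

    def test_first_passing_index_matches_scan(self):
        # geometric decay of successive changes
        deltas = [4.0, 2.0, 1.0, 0.4, 0.2, 0.1]
        E = np.zeros(5)
        snaps = [self._prof(E)]
        for d in deltas:
            E = E + d
            snaps.append(self._prof(E))
        report = fe.convergence_check(snaps, dF_tol=0.5)
        expected = next(k for k, d in enumerate(deltas) if d < 0.5)
        assert report["first_passing_index"] == expected

    def test_cutoff_excludes_high_regions(self):
        a = self._prof([0, 1, 50, 3])
        b = self._prof([0, 1, 80, 3])   # change only above the cutoff
        report = fe.convergence_check([a, b], fe_cutoff=40.0)
        assert report["dF_converged"]


class TestOrderedLda:
    STATES = ("s1", "s2", "s3", "s4", "s5")

    def _clusters(self, rng, n=30, dim=10, spacing=2.0, sd=0.5):
        g = rng.standard_normal(dim)
        g /= np.linalg.norm(g)
        X, labels = [], []
        for i, s in enumerate(self.STATES):
            X.append(i * spacing * g + rng.standard_normal((n, dim)) * sd)
            labels += [s] * n
        return np.vstack(X), np.array(labels), g

    def test_equal_means_objective_vanishes(self, rng):
        X_by = [rng.standard_normal((20, 6)) for _ in range(3)]
        X_by = [x - x.mean(axis=0) for x in X_by]
        w = rng.standard_normal(6)
        assert fe.ordered_lda_objective(w, X_by) == pytest.approx(0.0, abs=1e-12)

    def test_objective_scale_invariant(self, rng):
        X_by = [rng.standard_normal((15, 6)) + k for k in range(3)]
        w = rng.standard_normal(6)
        j1 = fe.ordered_lda_objective(w, X_by)
        j2 = fe.ordered_lda_objective(2.0 * w, X_by)
        assert j1 == pytest.approx(j2, rel=1e-12)

    def test_two_class_closed_form(self, rng):
        a = rng.standard_normal((40, 6)) @ np.diag(rng.uniform(0.5, 2, 6))
        b = a * 0.9 + rng.standard_normal((40, 6)) * 0.8 + 1.5
        X = np.vstack([a, b])
        labels = np.array(["a"] * 40 + ["b"] * 40)
        model = fe.fit_ordered_lda(X, labels, ("a", "b"), l2=0.0,
                                   n_restarts=50, seed=0)
        from statecoev.free_energy import _two_class_closed_form
        cf = _two_class_closed_form([a, b])
        cf /= np.linalg.norm(cf)
        assert abs(abs(model.w @ cf) - 1.0) < 1e-6

    def test_planted_direction_recovered(self, rng):
        X, labels, g = self._clusters(rng, n=50, dim=15)
        model = fe.fit_ordered_lda(X, labels, self.STATES, n_restarts=200,
                                   seed=0)
        assert abs(model.w @ g) >= 0.9
        assert model.ordered_fraction > 0.0

    def test_projected_means_ordered(self, rng):
        X, labels, _g = self._clusters(rng)
        model = fe.fit_ordered_lda(X, labels, self.STATES, n_restarts=100,
                                   seed=0)
        means = [model.project(X[labels == s]).mean() for s in self.STATES]
        assert np.all(np.diff(means) > 0)

    def test_unorderable_data_raises(self, rng):
        # three states whose means coincide cannot be strictly ordered
        X = np.vstack([rng.standard_normal((10, 4)) for _ in range(3)])
        X[:10] -= X[:10].mean(axis=0)
        X[10:20] -= X[10:20].mean(axis=0)
        X[20:] -= X[20:].mean(axis=0)
        labels = np.array(["a"] * 10 + ["b"] * 10 + ["c"] * 10)
        with pytest.raises(OrderingError):
            fe.fit_ordered_lda(X, labels, ("a", "b", "c"), n_restarts=10,
                               seed=0)

    def test_too_few_examples_rejected(self, rng):
        X = rng.standard_normal((3, 4))
        labels = np.array(["a", "a", "b"])
        with pytest.raises(InsufficientDataError):
            fe.fit_ordered_lda(X, labels, ("a", "b"))


class TestEnsembleIO:
    def test_round_trip(self, tmp_path):
        F = synthetic.double_well(10.0)
        ens = synthetic.make_biased_trajectory(F, F, n_frames=200,
                                               n_walkers=2, seed=1)
        path = tmp_path / "ens.dat"
        fe.write_ensemble(ens, path)
        again = fe.read_ensemble(path)
        assert np.allclose(again.xi, ens.xi, atol=1e-9)
        assert np.array_equal(again.walker, ens.walker)
        assert np.allclose(again.bias, ens.bias, atol=1e-9)
        assert again.temperature == ens.temperature

    def test_profile_round_trip(self, tmp_path, rng):
        E = rng.uniform(0, 5, 12)
        E -= E.min()
        prof = fe.FreeEnergyProfile(centers=np.linspace(0, 1, 12), E=E,
                                    se=np.full(12, 0.2),
                                    n_eff=np.full(12, 30.0), label="test")
        fe.write_profile(prof, tmp_path / "prof.tsv")
        again = fe.read_profile(tmp_path / "prof.tsv")
        assert np.allclose(again.E, prof.E, atol=1e-9)
        assert again.label == "test"

    def test_walker_ids_contiguity_enforced(self):
        with pytest.raises(DataError):
            BiasedEnsemble(time=np.array([0.0, 0.0]),
                           walker=np.array([0, 2]),
                           xi=np.zeros(2), bias=np.zeros(2))
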