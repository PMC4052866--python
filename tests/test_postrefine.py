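"""Per-pattern least-squares refinement and the outer driver."""

import copy

import numpy as np
import pandas as pd
import pytest

from stillref.geometry import SymmetryGroup, basis_components, hkl_pack
from stillref.postrefine import (
    NormalEquations,
    RefinementSettings,
    build_multiplicity_index,
    build_normal_equations,
    refine_pattern,
    residuals,
    run_cycles,
    select_refinable,
    solve_rescaled_svd,
    update_pattern_model,
)
from stillref.scaling import MergedIntensityTable, kabsch_scale_and_merge
from stillref.simulate import Pattern


@pytest.fixture(scope="module")
def full_size_dataset():
    """Two patterns at the full detector size (~1500 reflections each):
    the regime where the normal equations are generically rank 8."""
    from stillref.simulate import SimulationConfig, simulate_dataset

    return simulate_dataset(SimulationConfig(n_patterns=2, seed=21))


@pytest.fixture(scope="module")
def full_size_noiseless_perturbed():
    """Eight full-detector noiseless patterns with 0.1% basis errors:
    enough well-measured reflections per pattern that the geometry is
    determined up to the beam-axis rotation."""
    from stillref.simulate import SimulationConfig, simulate_dataset

    return simulate_dataset(SimulationConfig(n_patterns=8, seed=4, noise_sigma=0.0))


def reference_as_merged(reference, n_meas=2):
    """Present the true reference table as a merged table (oracle anchor)."""
    return MergedIntensityTable(
        keys=reference.keys,
        intensity=reference.intensity,
        n_meas=np.full(len(reference), n_meas),
        sigma=np.zeros(len(reference)),
        d=reference.d,
    )


class TestResiduals:
    def test_zero_at_truth_without_noise(self, noiseless_dataset):
        ds = noiseless_dataset
        pat = ds.patterns[0]
        refl = pat.reflections
        i_full, found = ds.reference.lookup(ds.config.symmetry.canonicalize(pat.hkl))
        d_i = residuals(
            refl["I"].to_numpy()[found],
            refl["L"].to_numpy()[found],
            refl["p"].to_numpy()[found],
            float(ds.truth.true_scales[0]),
            i_full[found],
        )
        np.testing.assert_allclose(d_i, 0.0, atol=1e-9 * refl["I"].abs().max())

    def test_zero_partiality_leaves_scaled_intensity(self):
        d_i = residuals(np.array([10.0]), np.array([2.0]), np.array([0.0]), 2.5, np.array([7.0]))
        assert d_i[0] == pytest.approx(10.0 / (2.5 * 2.0))

    def test_objective_larger_away_from_truth(self, noiseless_perturbed_dataset):
        """For almost all patterns, the sum of squared residuals at the
        true geometry is below that at the perturbed starting geometry."""
        ds = noiseless_perturbed_dataset
        merged = reference_as_merged(ds.reference)
        wins = 0
        for j, pat in enumerate(ds.patterns):
            refl = pat.reflections
            i_full, found = ds.reference.lookup(ds.config.symmetry.canonicalize(pat.hkl))
            g = float(ds.truth.true_scales[j])

            def ssr(basis):
                from stillref.partiality import excitation_distances, clamp_distances, partiality, lorentz

                s = pat.hkl @ basis.T
                geom = excitation_distances(s, ds.config.beam, ds.config.sphere_radius)
                p = partiality(clamp_distances(geom))
                L = lorentz(geom, ds.config.k_lorentz)
                d_i = residuals(refl["I"].to_numpy(), L, p, g, np.where(found, i_full, 0.0))
                return float(np.sum(d_i[found] ** 2))

            if ssr(ds.truth.true_bases[j]) < ssr(pat.basis):
                wins += 1
        assert wins >= 0.95 * len(ds.patterns)


class TestSelectRefinable:
    def test_enumerated_rules(self):
        """Five observations each crossing exactly one rejection rule."""
        sym = SymmetryGroup.identity_only()
        rows = [
            # h, k, l,   I, sigma,    p,   L
            (1, 0, 0, 10.0, 1.0, 0.50, 1.0),   # keeper
            (2, 0, 0, 2.0, 1.0, 0.50, 1.0),    # I < 3 sigma
            (3, 0, 0, 10.0, 1.0, 0.05, 1.0),   # p below cutoff
            (4, 0, 0, 10.0, 1.0, 0.50, 1.0),   # no second measurement anywhere
            (5, 0, 0, 10.0, 1.0, 0.50, 1.0),   # missing from merged table
        ]
        frame = pd.DataFrame(rows, columns=["h", "k", "l", "I", "sigma", "p", "L"])
        for extra in ("r_high", "r_low", "det_x", "det_y"):
            frame[extra] = 0.0
        frame["clamped_high"] = frame["clamped_low"] = False
        pat = Pattern(0, np.eye(3), frame)

        merged_hkl = np.array([[1, 0, 0], [2, 0, 0], [3, 0, 0], [4, 0, 0]])
        keys = hkl_pack(merged_hkl)
        order = np.argsort(keys)
        merged = MergedIntensityTable(
            keys=keys[order], intensity=np.full(4, 5.0)[order],
            n_meas=np.full(4, 2), sigma=np.zeros(4), d=np.full(4, 3.0),
        )
        # dataset multiplicity: >= 2 everywhere except (4,0,0)
        mult_keys = hkl_pack(np.array([[1, 0, 0], [2, 0, 0], [3, 0, 0], [4, 0, 0], [5, 0, 0]]))
        order = np.argsort(mult_keys)
        multiplicity = (mult_keys[order], np.array([2, 2, 2, 1, 2])[order])

        mask = select_refinable(pat, merged, sym, multiplicity)
        np.testing.assert_array_equal(mask, [True, False, False, False, False])

    def test_empty_selection_for_weak_pattern(self, small_dataset):
        ds = small_dataset
        pat = ds.patterns[0]
        weak = Pattern(0, pat.basis, pat.reflections.assign(I=0.0))
        merged = reference_as_merged(ds.reference)
        mult = build_multiplicity_index(ds.patterns, ds.config.symmetry)
        mask = select_refinable(weak, merged, ds.config.symmetry, mult)
        assert not mask.any()


class TestNormalEquations:
    def test_single_observation_rank_one(self, noiseless_dataset):
        ds = noiseless_dataset
        pat = ds.patterns[0]
        sel = pat.reflections["p"].to_numpy() > 0.3
        hkl = pat.hkl[sel][:1]
        i_full, _ = ds.reference.lookup(ds.config.symmetry.canonicalize(hkl))
        ne, p, d_i = build_normal_equations(
            hkl, pat.basis, ds.config,
            pat.reflections["I"].to_numpy()[sel][:1],
            pat.reflections["sigma"].to_numpy()[sel][:1],
            1.0, i_full,
        )
        assert np.linalg.matrix_rank(ne.matrix, tol=1e-12 * np.abs(ne.matrix).max()) == 1

    def test_matrix_matches_finite_difference_jacobian(self, noiseless_dataset):
        """Oracle: J from central differences of p (L frozen, as the
        model prescribes dL/dv = 0), then compare J^T J and -J^T dI."""
        from stillref.geometry import basis_from_components
        from stillref.partiality import partiality_gradients

        ds = noiseless_dataset
        cfg = ds.config
        pat = ds.patterns[1]
        sel = pat.reflections["p"].to_numpy() > 0.2
        hkl = pat.hkl[sel][:40]
        intensity = pat.reflections["I"].to_numpy()[sel][:40]
        sigma = pat.reflections["sigma"].to_numpy()[sel][:40]
        i_full, _ = ds.reference.lookup(cfg.symmetry.canonicalize(hkl))
        g = float(ds.truth.true_scales[1])
        ne, _, d_i = build_normal_equations(hkl, pat.basis, cfg, intensity, sigma, g, i_full)

        v0 = basis_components(pat.basis)
        jac = np.zeros((len(hkl), 9))
        for j in range(9):
            h = 1e-7 * abs(v0[j])
            vp, vm = v0.copy(), v0.copy()
            vp[j] += h
            vm[j] -= h
            pp, _ = partiality_gradients(hkl, basis_from_components(vp), cfg.beam, cfg.sphere_radius)
            pm, _ = partiality_gradients(hkl, basis_from_components(vm), cfg.beam, cfg.sphere_radius)
            jac[:, j] = -i_full * (pp - pm) / (2.0 * h)
        a_fd = jac.T @ jac
        scale = np.abs(ne.matrix).max()
        np.testing.assert_allclose(ne.matrix, a_fd, atol=1e-5 * scale)
        np.testing.assert_allclose(ne.rhs, -jac.T @ d_i, atol=1e-5 * np.abs(ne.rhs).max())

    def test_all_clamped_gives_zero_matrix(self):
        ne = NormalEquations(matrix=np.zeros((9, 9)), rhs=np.zeros(9))
        step, eliminated = solve_rescaled_svd(ne)
        np.testing.assert_array_equal(step, np.zeros(9))
        assert eliminated == 0  # no active parameters at all


class TestSolveRescaledSvd:
    def test_identity_system(self):
        ne = NormalEquations(matrix=np.eye(9), rhs=np.eye(9)[0])
        step, eliminated = solve_rescaled_svd(ne)
        np.testing.assert_allclose(step, np.eye(9)[0], atol=1e-12)
        assert eliminated == 0

    def test_matches_direct_solve_on_spd_matrix(self, rng):
        """Oracle: dense solve of a well-conditioned random SPD system."""
        for _ in range(5):
            m = rng.normal(size=(9, 9))
            a = m @ m.T + 9 * np.eye(9)
            b = rng.normal(size=9)
            ne = NormalEquations(matrix=a, rhs=b)
            step, eliminated = solve_rescaled_svd(ne)
            assert eliminated == 0
            np.testing.assert_allclose(step, np.linalg.solve(a, b), rtol=1e-8)

    def test_real_pattern_eliminates_exactly_one(self, full_size_dataset):
        """Generic snapshot normal equations are rank 8: rotating the
        crystal about the beam axis never changes any partiality."""
        ds = full_size_dataset
        pat = ds.patterns[0]
        update_pattern_model(pat, ds.config)
        sel = (pat.reflections["p"].to_numpy() >= 0.1) & (
            pat.reflections["I"].to_numpy() >= 3 * pat.reflections["sigma"].to_numpy()
        )
        hkl = pat.hkl[sel]
        i_full, found = ds.reference.lookup(ds.config.symmetry.canonicalize(hkl))
        ne, _, _ = build_normal_equations(
            hkl[found], pat.basis, ds.config,
            pat.reflections["I"].to_numpy()[sel][found],
            pat.reflections["sigma"].to_numpy()[sel][found],
            1.0, i_full[found],
        )
        step, eliminated = solve_rescaled_svd(ne, eig_frac=1e-6)
        assert eliminated == 1

    def test_step_avoids_beam_axis_rotation_direction(self, full_size_dataset):
        """The analytic null direction (infinitesimal rotation about z)
        must be absent from the step in the rescaled metric."""
        ds = full_size_dataset
        pat = ds.patterns[1]
        update_pattern_model(pat, ds.config)
        sel = (pat.reflections["p"].to_numpy() >= 0.1) & (
            pat.reflections["I"].to_numpy() >= 3 * pat.reflections["sigma"].to_numpy()
        )
        hkl = pat.hkl[sel]
        i_full, found = ds.reference.lookup(ds.config.symmetry.canonicalize(hkl))
        ne, _, _ = build_normal_equations(
            hkl[found], pat.basis, ds.config,
            pat.reflections["I"].to_numpy()[sel][found],
            pat.reflections["sigma"].to_numpy()[sel][found],
            1.0, i_full[found],
        )
        step, eliminated = solve_rescaled_svd(ne, eig_frac=1e-6)
        assert eliminated == 1
        b = pat.basis
        null = np.array([-b[1, 0], b[0, 0], 0.0, -b[1, 1], b[0, 1], 0.0, -b[1, 2], b[0, 2], 0.0])
        # the solver works in coordinates y = step / D; the null direction there is D * null
        d = ne.rescale
        y = np.divide(step, d, out=np.zeros(9), where=d > 0)
        n_scaled = null / np.where(d > 0, d, np.inf)
        cosine = abs(np.dot(y, n_scaled)) / (np.linalg.norm(y) * np.linalg.norm(n_scaled))
        assert cosine < 1e-8


class TestRefinePattern:
    def test_converges_immediately_at_truth(self, noiseless_dataset_copy):
        ds = noiseless_dataset_copy
        merged = reference_as_merged(ds.reference)
        mult = build_multiplicity_index(ds.patterns, ds.config.symmetry)
        pat = ds.patterns[0]
        update_pattern_model(pat, ds.config)
        res = refine_pattern(
            pat, merged, float(ds.truth.true_scales[0]), ds.config, mult
        )
        assert res.termination == "converged"
        assert res.n_inner_iterations == 1
        assert res.max_delta_p[0] < 0.01

    def test_refinement_approaches_truth_against_reference(self, full_size_noiseless_perturbed):
        """Oracle anchor: with the true intensities as target, nearly all
        perturbed patterns end closer to the true basis than they began."""
        ds = copy.copy(full_size_noiseless_perturbed)
        ds.patterns = copy.deepcopy(full_size_noiseless_perturbed.patterns)
        merged = reference_as_merged(ds.reference)
        mult = build_multiplicity_index(ds.patterns, ds.config.symmetry)
        closer = 0
        for j, pat in enumerate(ds.patterns):
            update_pattern_model(pat, ds.config)
            tb = ds.truth.true_bases[j]
            before = np.linalg.norm(pat.basis - tb)
            refine_pattern(pat, merged, float(ds.truth.true_scales[j]), ds.config, mult)
            after = np.linalg.norm(pat.basis - tb)
            if after < before:
                closer += 1
        assert closer >= 0.9 * len(ds.patterns)

    def test_step_zeroing_partialities_is_reverted(self, small_dataset):
        """An absurd scale estimate drives a huge first step; the step
        would extinguish most partialities and must be rolled back."""
        ds = small_dataset
        pat = copy.deepcopy(ds.patterns[1])
        update_pattern_model(pat, ds.config)
        merged = reference_as_merged(ds.reference)
        mult = build_multiplicity_index(ds.patterns, ds.config.symmetry)
        basis_before = pat.basis.copy()
        res = refine_pattern(pat, merged, 1e-4, ds.config, mult)  # G far too small
        if res.reverted:
            np.testing.assert_array_equal(pat.basis, basis_before)
            assert res.termination == "step reverted"
        else:  # the safeguard never fired: refinement must at least terminate cleanly
            assert res.termination in ("converged", "max iterations", "selection exhausted")

    def test_skipped_pattern_keeps_basis(self, small_dataset):
        ds = small_dataset
        pat = copy.deepcopy(ds.patterns[0])
        pat.reflections["I"] = 0.0  # nothing passes the 3-sigma cut
        merged = reference_as_merged(ds.reference)
        mult = build_multiplicity_index(ds.patterns, ds.config.symmetry)
        before = pat.basis.copy()
        res = refine_pattern(pat, merged, 1.0, ds.config, mult)
        assert res.termination == "empty selection"
        np.testing.assert_array_equal(pat.basis, before)


class TestRunCycles:
    def test_zero_cycles_equals_plain_scale_and_merge(self, small_dataset):
        ds_a = copy.deepcopy(small_dataset)
        ds_b = copy.deepcopy(small_dataset)
        hist = run_cycles(ds_a.patterns, ds_a.config, n_cycles=0)
        for pat in ds_b.patterns:
            update_pattern_model(pat, ds_b.config)
        scales, merged = kabsch_scale_and_merge(ds_b.patterns, ds_b.config.symmetry, n_rounds=3)
        np.testing.assert_array_equal(hist.final_merged.keys, merged.keys)
        np.testing.assert_allclose(hist.final_merged.intensity, merged.intensity, rtol=1e-12)
        np.testing.assert_allclose(hist.final_scales.scales, scales.scales, rtol=1e-12)

    def test_p_one_mode_forces_unit_partialities(self, small_dataset):
        ds = copy.deepcopy(small_dataset)
        run_cycles(ds.patterns, ds.config, n_cycles=2, mode="p_one")
        for pat in ds.patterns[:3]:
            assert (pat.reflections["p"] == 1.0).all()

    def test_no_scaling_mode_uses_unit_scales(self, small_dataset):
        ds = copy.deepcopy(small_dataset)
        hist = run_cycles(ds.patterns, ds.config, n_cycles=0, mode="no_scaling")
        np.testing.assert_array_equal(hist.final_scales.scales, np.ones(len(ds.patterns)))

    def test_objective_nonincreasing_for_most_patterns(self, noiseless_perturbed_copy):
        """Accepted Gauss-Newton iterations lower the objective for the
        overwhelming majority of patterns (no damping is used, so rare
        overshoots are tolerated)."""
        ds = noiseless_perturbed_copy
        merged = reference_as_merged(ds.reference)
        mult = build_multiplicity_index(ds.patterns, ds.config.symmetry)
        improved = 0
        total = 0
        for j, pat in enumerate(ds.patterns):
            update_pattern_model(pat, ds.config)
            refl = pat.reflections
            i_full, found = ds.reference.lookup(ds.config.symmetry.canonicalize(pat.hkl))
            g = float(ds.truth.true_scales[j])

            def ssr():
                d_i = residuals(
                    refl["I"].to_numpy()[found],
                    refl["L"].to_numpy()[found],
                    refl["p"].to_numpy()[found],
                    g, i_full[found],
                )
                return float(np.sum(d_i**2))

            before = ssr()
            res = refine_pattern(pat, merged, g, ds.config, mult)
            update_pattern_model(pat, ds.config)
            if res.n_inner_iterations == 0 or res.reverted:
                continue
            total += 1
            if ssr() <= before * (1 + 1e-12):
                improved += 1
        assert total > 0
        assert improved >= 0.95 * total
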