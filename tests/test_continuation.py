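"""Fixed points, branches, bifurcation detection, the Hopf line."""

import numpy as np
import pytest

import ionhh as ih
from ionhh.continuation import find_fixed_point


def branch_K_e(params, x, p):
    return params.K_e0 - params.vol_ratio * (x[..., 2] - params.K_i0) + p


class TestFixedPoints:
    def test_physiological_point_stable(self, params, rest_closed):
        fp = find_fixed_point(rest_closed, params)
        assert fp.stable
        assert np.all(fp.eigvals.real < 0)
        assert fp.x[0] == pytest.approx(rest_closed.V, abs=1e-8)

    def test_fes_point_from_depolarized_guess(self, params):
        guess = ih.DynamicState("closed", V=-25.0, n=0.55,
                                K_i=params.K_i0, Cl_i=30.0, dNK=20.0)
        fp = find_fixed_point(guess, params)
        ke = branch_K_e(params, fp.x, fp.p)
        assert fp.x[0] > -50.0        # depolarized
        assert ke > 20.0              # strong ECS potassium elevation
        assert fp.stable

    def test_forward_integration_oracle(self, params, rest_closed):
        """500 s of relaxation from a perturbed state lands on the Newton
        point (stable fixed points attract)."""
        fp = find_fixed_point(rest_closed, params)
        start = rest_closed.replace(V=rest_closed.V + 0.1)
        traj = ih.simulate(params, "closed", t_end=500.0,
                           initial_state=start, dt_out=1.0)
        final = traj.y[-1, :4]
        np.testing.assert_allclose(final, fp.x, rtol=0, atol=1e-6)

    def test_nonconvergence_reports_history(self, params):
        from ionhh.continuation import NewtonError, newton
        with pytest.raises(NewtonError) as err:
            newton(lambda x: np.array([x[0] ** 2 + 1.0]),
                   np.array([1.0]), tol=1e-12, max_iter=5)
        assert len(err.value.residual_history) >= 1


class TestDnkBranch:
    def test_bifurcation_inventory(self, dnk_branch):
        """Four Hopf points and two folds, starting HB1 then LP1, ending in
        the restabilizing HB4.  (The middle-branch cluster HB2/LP2/HB3 spans
        ~1 mM; its internal order is not resolvable at reimplementation
        precision.)"""
        labels = dnk_branch.labels()
        assert labels[0] == "HB1"
        assert labels[1] == "LP1"
        assert sorted(labels) == ["HB1", "HB2", "HB3", "HB4", "LP1", "LP2"]
        assert labels[-1] == "HB4"

    def test_fes_stable_after_hb4(self, params, dnk_branch):
        hb4 = next(b for b in dnk_branch.bifurcations if b.label == "HB4")
        after = dnk_branch.p > hb4.p + 0.5
        seg = dnk_branch.stable[after & (branch_K_e(
            params, dnk_branch.x, dnk_branch.p) > 15.0)]
        assert seg.size > 0 and np.all(seg)

    def test_s_shaped_with_outer_stable_branches(self, params, dnk_branch):
        ke = branch_K_e(params, dnk_branch.x, dnk_branch.p)
        # physiological branch: low K_e, stable; FES branch: high K_e, stable
        phys = dnk_branch.stable & (ke < 7.0)
        fes = dnk_branch.stable & (ke > 21.0)
        mid = ~dnk_branch.stable
        assert phys.sum() > 10 and fes.sum() > 10 and mid.sum() > 10
        # folded: the parameter range of the unstable middle overlaps both
        assert dnk_branch.p[mid].min() < dnk_branch.p[phys].max()
        assert dnk_branch.p[mid].max() > dnk_branch.p[fes].min()

    def test_eigenvalues_consistent_with_stability_flag(self, dnk_branch):
        max_re = dnk_branch.eigvals.real.max(axis=1)
        np.testing.assert_array_equal(dnk_branch.stable, max_re < 0)

    def test_folds_are_parameter_extrema(self, dnk_branch):
        for b in dnk_branch.bifurcations:
            if b.kind != "LP":
                continue
            i = np.argmin(np.abs(dnk_branch.p - b.p)
                          + np.abs(dnk_branch.x[:, 0] - b.x[0]))
            lo = max(0, i - 4)
            hi = min(len(dnk_branch.p), i + 5)
            window = dnk_branch.p[lo:hi]
            assert (b.p >= window.min() - 0.05 and b.p <= window.max() + 0.05)
            # local extremum: interior points lie on one side
            assert (np.abs(window - b.p).max() < 2.0)

    @staticmethod
    def _physiological_fp(params, dnk_branch, dnk):
        """Fixed point on the physiological branch at a given dNK, seeded
        from the nearest continuation point."""
        phys = np.nonzero(dnk_branch.x[:, 0] < -55.0)[0]
        i = phys[np.argmin(np.abs(dnk_branch.p[phys] - dnk))]
        guess = ih.DynamicState("closed", *dnk_branch.x[i], dNK=dnk)
        return find_fixed_point(guess, params)

    def test_detection_soundness_at_hb1(self, params, dnk_branch):
        """Just below HB1 (0.1 mM) perturbations of the resting point decay;
        just above they grow into sustained oscillation."""
        hb1 = dnk_branch.bifurcations[0]
        for delta, attracts in ((-0.1, True), (+0.1, False)):
            fp = self._physiological_fp(params, dnk_branch, hb1.p + delta)
            start = ih.DynamicState(
                "closed", fp.x[0] + 0.5, fp.x[1], fp.x[2], fp.x[3], dNK=fp.p)
            traj = ih.simulate(params, "closed", t_end=400.0,
                               initial_state=start, dt_out=0.25)
            early = traj.times < 120.0
            late = traj.times > 300.0
            amp_early = np.max(np.abs(traj.V[early] - fp.x[0]))
            amp_late = np.max(np.abs(traj.V[late] - fp.x[0]))
            if attracts:
                assert amp_late < 0.3 * amp_early
            else:
                # the orbit leaves the fixed point and saturates on the
                # nearby limit cycle: spiking-scale amplitude
                assert amp_late > 5.0

    def test_branch_end_is_ignition_threshold(self, params, dnk_branch):
        """Holding the potassium content below the physiological branch end
        keeps the neuron resting; holding it beyond the end (and past the
        narrow oscillatory window) drives it to FES."""
        hb1 = dnk_branch.bifurcations[0]
        fp_lo = self._physiological_fp(params, dnk_branch, hb1.p - 0.5)
        start_lo = ih.DynamicState(
            "closed", fp_lo.x[0] + 1.0, fp_lo.x[1], fp_lo.x[2], fp_lo.x[3],
            dNK=fp_lo.p)
        tr_lo = ih.simulate(params, "closed", t_end=400.0,
                            initial_state=start_lo, dt_out=0.5)
        assert tr_lo.V[-1] < -55.0
        start_hi = ih.DynamicState(
            "closed", fp_lo.x[0], fp_lo.x[1], fp_lo.x[2], fp_lo.x[3],
            dNK=hb1.p + 3.0)
        tr_hi = ih.simulate(params, "closed", t_end=400.0,
                            initial_state=start_hi, dt_out=0.5)
        last = tr_hi.V[tr_hi.times > 350.0]
        assert np.all(last > -50.0)  # ended on FES


class TestKbathBranch:
    def test_fixed_points_pinned_to_bath(self, params, kbath_branch):
        """Diffusive coupling makes K_e = K_bath a fixed-point condition."""
        ke = params.K_e0 - params.vol_ratio * (
            kbath_branch.x[:, 2] - params.K_i0) + kbath_branch.x[:, 4]
        np.testing.assert_allclose(ke, kbath_branch.p, atol=1e-9)

    def test_hb_pattern_with_single_restabilization(self, kbath_branch):
        labels = kbath_branch.labels()
        hbs = [l for l in labels if l.startswith("HB")]
        assert hbs[0] == "HB1" and hbs[-1] == "HB4"
        hb4 = next(b for b in kbath_branch.bifurcations if b.label == "HB4")
        after = kbath_branch.p > hb4.p + 0.2
        assert np.all(kbath_branch.stable[after])
        # no further bifurcation above HB4
        assert all(b.p <= hb4.p + 1e-6 for b in kbath_branch.bifurcations)

    def test_matches_closed_model_spectrum(self, params, dnk_branch,
                                           kbath_branch):
        """The bath model's Hopf points sit at the K_e values of the closed
        model's (the added bath direction only appends a relaxation mode)."""
        ke_closed = {b.label: branch_K_e(params, b.x, b.p)
                     for b in dnk_branch.bifurcations if b.kind == "HB"}
        for b in kbath_branch.bifurcations:
            if b.kind == "HB":
                # HB2/HB3 sit in a near-degenerate cluster (the crossing
                # pair's frequency almost vanishes) where the appended slow
                # bath mode shifts the crossing slightly
                tol = 0.01 if b.label in ("HB1", "HB4") else 0.15
                assert b.p == pytest.approx(ke_closed[b.label], abs=tol)


class TestHopfLine:
    def test_one_hopf_per_grid_value(self, hopf_line):
        assert len(hopf_line) == 7
        for cl, hb in hopf_line:
            assert hb is not None, f"no Hopf point at Cl_i={cl}"
            assert hb.kind == "HB"

    def test_monotone_in_chloride(self, hopf_line):
        dnk = [hb.p for _, hb in hopf_line]
        assert np.all(np.diff(dnk) > 0)

    def test_sd_repolarization_near_hopf_line(self, params, hopf_line,
                                              sd_ep):
        """The buffered SD trajectory leaves the FES plateau where its slow
        state (Cl_i, dNK) crosses the computed Hopf line."""
        tr = sd_ep.trajectory
        i = np.searchsorted(tr.times, sd_ep.offset)
        cl_off = tr.Cl_i[i]
        dnk_off = tr.dNK[i]
        cls = np.array([cl for cl, _ in hopf_line])
        dnks = np.array([hb.p for _, hb in hopf_line])
        dnk_line = np.interp(cl_off, cls, dnks)
        assert abs(dnk_off - dnk_line) < 2.0
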