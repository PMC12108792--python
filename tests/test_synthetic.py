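import numpy as np
import pytest

import nucdamage as nd
from nucdamage.synthetic import CompositionError, _central_groove_angle


class TestBuildBdna:
    def test_invalid_sequence(self):
        with pytest.raises(ValueError):
            nd.build_bdna("ACGX")
        with pytest.raises(ValueError):
            nd.build_bdna("A")

    def test_helical_phase_identity(self):
        # bp i and i+10 differ in phase by 360*10/10.4 deg
        m = nd.build_bdna("ACGTACGTACGTACG")
        c1 = [m.residue("I", k).atom("C1'").coord for k in (1, 11)]
        phases = [np.degrees(np.arctan2(c[1], c[0])) for c in c1]
        dphi = (phases[1] - phases[0]) % 360.0
        assert dphi == pytest.approx((360.0 * 10 / 10.4) % 360.0, abs=1e-6)

    def test_mean_twist_matches_params(self):
        params = nd.HelixParams(bp_per_turn=10.4)
        m = nd.build_bdna("ACGTACGTACGTACGTACGT", params)
        phases = []
        for k in range(1, 21):
            c = m.residue("I", k).atom("C1'").coord
            phases.append(np.arctan2(c[1], c[0]))
        steps = np.degrees(np.diff(np.unwrap(phases)))
        assert steps.mean() == pytest.approx(params.twist_deg, abs=0.01)

    def test_rise_exact(self):
        m = nd.build_bdna("ACGTACGT")
        z = [m.residue("I", k).atom("C1'").coord[2] for k in range(1, 9)]
        np.testing.assert_allclose(np.diff(z), 3.4, atol=1e-12)

    def test_phi_on_central_bp_in_band(self):
        # paper-anchored calibration: relaxed B-DNA local twist 60-70 deg
        m = nd.build_bdna("ACGTACGTACGTACG")
        mod, site = nd.make_ssb(m, ("I", 8))
        assert 60.0 <= nd.local_twist(mod, None, site) <= 70.0

    def test_param_validation(self):
        with pytest.raises(ValueError):
            nd.HelixParams(rise=-1)
        with pytest.raises(ValueError):
            nd.HelixParams(bp_per_turn=5.0)  # twist 72 > 60

    def test_antiparallel_pairing(self):
        m = nd.build_bdna("ACGT")
        pairs = nd.antiparallel_pairs(m, ("I", "J"))
        assert [(a.resname, b.resname) for a, b in pairs] == [
            ("DA", "DT"), ("DC", "DG"), ("DG", "DC"), ("DT", "DA")]


class TestWrapSuperhelix:
    def test_shl_span(self, nucleosome_wrap):
        _, smap = nucleosome_wrap
        vals = np.array(list(smap.shl_of.values()))
        # path-length arithmetic: 145 bp / 2 / 10.4 = 6.97
        assert vals.max() == pytest.approx(6.97, abs=0.5)
        assert vals.min() == pytest.approx(-6.97, abs=0.5)

    def test_contact_points_14(self, nucleosome_wrap):
        wrap, smap = nucleosome_wrap
        assert len(nd.contact_points(smap, wrap)) == 14

    def test_unwrapped_limit_reproduces_duplex(self):
        dup = nd.build_bdna("ACGTACGTACGTACGTACGTA")
        big = nd.SuperhelixParams(radius=1e7, pitch=25.9)
        wrapped = nd.wrap_superhelix(dup, big, align="duplex")
        assert np.abs(wrapped.coords() - dup.coords()).max() < 0.1

    def test_self_intersection_rejected(self):
        dup = nd.build_bdna("ACGTACGTAC")
        with pytest.raises(ValueError):
            nd.wrap_superhelix(dup, nd.SuperhelixParams(radius=10.0))

    def test_handedness_param(self):
        with pytest.raises(ValueError):
            nd.SuperhelixParams(handedness="right")

    def test_dyad_minor_groove_outward(self, nucleosome_wrap):
        wrap, smap = nucleosome_wrap
        # the pre-rotation puts the dyad minor groove on the outward side:
        # contact points (inward grooves) sit at half-integral SHL
        cps = np.array(nd.contact_points(smap, wrap))
        frac = np.abs(cps - np.round(cps))
        assert np.median(frac) > 0.3


class TestMakeTrajectory:
    def test_no_signals_zero_noise_identity(self, duplex21):
        traj, truth = nd.make_trajectory(duplex21, [], n_frames=4, seed=0)
        for f in traj.frames:
            np.testing.assert_array_equal(f, duplex21.coords())
        assert truth.empty

    def test_dg_ramp_exact(self, ssb_duplex):
        model, site = ssb_duplex
        sched = np.linspace(1.2, 2.2, 60)
        traj, truth = nd.make_trajectory(
            model, [nd.DeformationSignal("dg", sched, site=site)], seed=0)
        dg = nd.gap_distance_series(traj, site).values
        assert np.abs(dg - sched).max() < 1e-3
        assert np.abs(truth.achieved.values - sched).max() < 1e-9

    def test_noise_sigma_in_band(self, ssb_duplex):
        model, site = ssb_duplex
        sched = np.linspace(1.2, 2.2, 400)
        traj, _ = nd.make_trajectory(
            model, [nd.DeformationSignal("dg", sched, noise_sigma=0.02,
                                         site=site)], seed=42)
        dg = nd.gap_distance_series(traj, site).values
        resid = dg - sched
        assert 0.01 <= resid.std() <= 0.04

    def test_bit_identical_regeneration(self, ssb_duplex):
        model, site = ssb_duplex
        sig = [nd.DeformationSignal("dg", np.linspace(1.2, 2.0, 20),
                                    noise_sigma=0.05, site=site)]
        t1, _ = nd.make_trajectory(model, sig, seed=7)
        t2, _ = nd.make_trajectory(model, sig, seed=7)
        for f1, f2 in zip(t1.frames, t2.frames):
            np.testing.assert_array_equal(f1, f2)

    def test_conflicting_signals_rejected(self, ssb_duplex):
        model, site = ssb_duplex
        s1 = nd.DeformationSignal("dg", np.ones(5), site=site)
        model2, site2 = nd.make_ssb(
            nd.build_bdna("ACGTACGTACGTACGTACGTA"), ("I", 11))
        # two dg signals on the same site move the same atoms
        s2 = nd.DeformationSignal("dg", np.ones(5) * 1.5, site=site)
        with pytest.raises(CompositionError):
            nd.make_trajectory(model, [s1, s2], seed=0)

    def test_phi_dg_same_site_allowed(self, ssb_duplex):
        model, site = ssb_duplex
        traj, _ = nd.make_trajectory(
            model,
            [nd.DeformationSignal("phi", np.full(5, 50.0), site=site),
             nd.DeformationSignal("dg", np.full(5, 1.5), site=site)], seed=0)
        assert nd.local_twist(model, traj.frames[-1], site) == pytest.approx(50, abs=1e-6)
        assert nd.gap_distance(model, traj.frames[-1], site) == pytest.approx(1.5, abs=1e-6)

    def test_parameter_recovery_within_3sigma(self, nucleosome_wrap):
        # acceptance surface: every injected schedule recovered < 3x noise
        wrap, smap = nucleosome_wrap
        model, site = nd.make_ssb(wrap.copy(), ("I", 21))
        n = 150
        dg_s = np.linspace(1.3, 2.1, n)
        phi_s = np.linspace(40.0, 85.0, n)
        dw_s = np.linspace(1.15, 1.7, n)
        sigma_d, sigma_phi = 0.02, 1.0
        traj, _ = nd.make_trajectory(
            model,
            [nd.DeformationSignal("phi", phi_s, noise_sigma=sigma_phi, site=site),
             nd.DeformationSignal("dg", dg_s, noise_sigma=sigma_d, site=site),
             nd.DeformationSignal("dw", dw_s, noise_sigma=sigma_d, site=site)],
            seed=5, shlmap=smap)
        dg = nd.gap_distance_series(traj, site).values
        phi = nd.local_twist_series(traj, site).values
        dw = nd.gyre_gaping_series(traj, site, smap).values
        assert np.abs(dg - dg_s).max() < 3 * sigma_d + 1e-6
        assert np.abs(dw - dw_s).max() < 3 * sigma_d + 1e-6
        assert np.abs(phi - phi_s).max() < 3 * sigma_phi + 1e-6


class TestProbes:
    def test_constant_schedule(self, duplex21):
        probed = nd.place_probe_residues(
            duplex21, [nd.ProbeSpec("LEU151", ("I", 11, "C3'"), 0.5)])
        d = nd.pair_distance(probed, None,
                             nd.select(probed, "chain P and resid 151"),
                             nd.select(probed, "chain I and resid 11 and name C3'"))
        assert d == pytest.approx(0.5, abs=1e-3)

    def test_two_probes_one_anchor(self, duplex21):
        probed = nd.place_probe_residues(
            duplex21,
            [nd.ProbeSpec("LEU151", ("I", 11, "C3'"), 0.5, chain_id="P"),
             nd.ProbeSpec("PHE44", ("I", 11, "C3'"), 0.9, chain_id="Q")])
        for chain, want in (("P", 0.5), ("Q", 0.9)):
            d = nd.pair_distance(probed, None,
                                 nd.select(probed, f"chain {chain}"),
                                 nd.select(probed, "chain I and resid 11 and name C3'"))
            assert d == pytest.approx(want, abs=1e-3)

    def test_negative_distance_rejected(self, duplex21):
        with pytest.raises(ValueError):
            nd.place_probe_residues(
                duplex21, [nd.ProbeSpec("LEU151", ("I", 11, "C3'"), -0.2)])

    def test_band_schedule_respected(self, duplex21):
        # mimics the reported 0.4-0.7 nm contact band
        probed = nd.place_probe_residues(
            duplex21, [nd.ProbeSpec("LEU151", ("I", 11, "C3'"), 0.55)])
        rng = np.random.default_rng(1)
        sched = 0.55 + 0.15 * np.sin(np.linspace(0, 6 * np.pi, 80))
        traj, _ = nd.make_trajectory(
            probed, [nd.DeformationSignal(
                "probe_distance", sched,
                anchors={"probe": ("P", 151), "anchor": ("I", 11, "C3'")})],
            seed=2)
        s = nd.pair_distance_series(traj, "chain P and resid 151",
                                    "chain I and resid 11 and name C3'")
        assert s.values.min() >= 0.4 - 1e-6
        assert s.values.max() <= 0.7 + 1e-6


class TestGrooveCalibration:
    def test_groove_angle_finite(self, duplex21):
        assert np.isfinite(_central_groove_angle(duplex21))
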