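import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import nucdamage as nd
from nucdamage.observables import (AnchorError, dihedral_deg, series_stats,
                                   correlate)
from nucdamage.structure_io import Atom, Chain, Residue, StructureModel

from conftest import random_rotation


def atoms_model(positions, names=None, resname="GLY", chain="A"):
    names = names or [f"A{i}" for i in range(len(positions))]
    res = Residue(resname, 1, chain,
                  [Atom(n, "C", p) for n, p in zip(names, positions)])
    return StructureModel([Chain(chain, [res])])


class TestGapDistance:
    def test_coincident_is_zero(self, ssb_duplex):
        model, site = ssb_duplex
        coords = model.coords()
        coords[site.five_c3_index(model)] = coords[site.three_c3_index(model)]
        assert nd.gap_distance(model, coords, site) == 0.0

    def test_12_angstrom_is_1p2_nm(self, ssb_duplex):
        model, site = ssb_duplex
        coords = model.coords()
        coords[site.three_c3_index(model)] = [0.0, 0.0, 0.0]
        coords[site.five_c3_index(model)] = [12.0, 0.0, 0.0]
        assert nd.gap_distance(model, coords, site) == pytest.approx(1.2)

    def test_symmetric(self, ssb_duplex):
        model, site = ssb_duplex
        d = nd.gap_distance(model, None, site)
        swapped = nd.DamageSite(
            kind="ssb", anchor=site.anchor,
            ends={"five": site.ends["three"], "three": site.ends["five"]},
            unpaired=site.unpaired, phi_anchors=site.phi_anchors)
        assert nd.gap_distance(model, None, swapped) == pytest.approx(d)

    def test_missing_anchor_names_residue(self, ssb_duplex):
        model, site = ssb_duplex
        res = model.residue(*site.ends["three"][:2])
        res.atoms = [a for a in res.atoms if a.name != "C3'"]
        model.invalidate()
        with pytest.raises(AnchorError, match=str(site.ends["three"][1])):
            nd.gap_distance(model, None, site)


class TestLocalTwist:
    def test_coplanar_cis_is_zero(self):
        m = atoms_model([[0, 1, 0], [0, 0, 0], [1, 0, 0], [1, 1, 0]])
        a, b, c, d = (m.coords()[i] for i in range(4))
        assert abs(dihedral_deg(a, b, c, d)) < 1e-9

    def test_ideal_bdna_60_to_70(self, duplex21):
        model, site = nd.make_ssb(duplex21.copy(), ("I", 11))
        phi = nd.local_twist(model, None, site)
        assert 60.0 <= phi <= 70.0

    def test_injected_45_recovered(self, ssb_duplex):
        model, site = ssb_duplex
        sched = np.full(3, 45.0)
        traj, _ = nd.make_trajectory(
            model, [nd.DeformationSignal("phi", sched, site=site)], seed=0)
        phi = nd.local_twist(model, traj.frames[0], site)
        assert phi == pytest.approx(45.0, abs=1.0)

    def test_range_0_180(self, ssb_duplex):
        model, site = ssb_duplex
        assert 0.0 <= nd.local_twist(model, None, site) <= 180.0


class TestGyreGaping:
    def test_parallel_duplexes_constructed(self):
        # two P atoms 11.5 A apart in adjacent gyres -> dw = 1.15 nm
        m = atoms_model([[0, 0, 0]], names=["P"], resname="DA")
        res2 = Residue("DG", 2, "A", [Atom("P", "P", [0, 0, 11.5])])
        m.chains[0].residues.append(res2)
        m.invalidate()
        smap = nd.SHLMap(axis=np.array([0, 0, 1.0]), center=np.zeros(3),
                         dyad=("A", 1), shl_of={("A", 1): -5.0, ("A", 2): 2.0},
                         gyre_of={("A", 1): "lower", ("A", 2): "upper"})
        dw = nd.gyre_gaping(m, None, ("A", 1), smap)
        assert dw == pytest.approx(1.15)

    def test_injected_drift_recovered(self, nucleosome_wrap):
        wrap, smap = nucleosome_wrap
        model, site = nd.make_ssb(wrap.copy(), ("I", 21))
        sched = np.linspace(1.15, 1.6, 30)
        traj, _ = nd.make_trajectory(
            model, [nd.DeformationSignal("dw", sched, site=site)],
            seed=2, shlmap=smap)
        dw = nd.gyre_gaping_series(traj, site, smap).values
        assert abs(dw[0] - 1.15) < 0.05
        assert abs(dw[-1] - 1.6) < 0.05

    def test_dyad_site_rejected(self, nucleosome_wrap):
        wrap, smap = nucleosome_wrap
        # a fake one-gyre map: nothing on the other side
        solo = {k: "upper" for k in smap.gyre_of}
        smap_solo = nd.SHLMap(axis=smap.axis, center=smap.center,
                              dyad=smap.dyad, shl_of=smap.shl_of,
                              gyre_of=solo, pairs=smap.pairs)
        with pytest.raises(AnchorError):
            nd.gyre_gaping(wrap, None, ("I", 73), smap_solo)


class TestPairDistance:
    def test_identical_selection_com_zero(self, duplex21):
        s = nd.select(duplex21, "chain I and resid 5")
        assert nd.pair_distance(duplex21, None, s, s, mode="com") == 0.0

    def test_two_atoms_5A(self):
        m = atoms_model([[0, 0, 0], [5, 0, 0]], names=["CA", "CB"])
        a = nd.select(m, "name CA")
        b = nd.select(m, "name CB")
        assert nd.pair_distance(m, None, a, b, "min") == pytest.approx(0.5)
        assert nd.pair_distance(m, None, a, b, "com") == pytest.approx(0.5)

    def test_symmetric(self, duplex21):
        a = nd.select(duplex21, "chain I and resid 3")
        b = nd.select(duplex21, "chain J and resid 7")
        for mode in ("min", "com"):
            assert (nd.pair_distance(duplex21, None, a, b, mode)
                    == pytest.approx(nd.pair_distance(duplex21, None, b, a, mode)))

    def test_empty_selection_rejected(self, duplex21):
        with pytest.raises(AnchorError):
            nd.pair_distance(duplex21, None,
                             nd.select(duplex21, "chain Z"),
                             nd.select(duplex21, "chain I"))


class TestHBonds:
    def test_present_absent_threshold(self, duplex21):
        crit = nd.HBondCriteria(max_DA_distance=3.5)
        base = duplex21.coords()
        i = duplex21.atom_index("I", 5, "C3'")
        j = duplex21.atom_index("I", 6, "C3'")
        frames = []
        dists = np.linspace(2.5, 6.0, 36)
        for d in dists:
            f = base.copy()
            f[j] = f[i] + [d, 0, 0]
            frames.append(f)
        traj = nd.Trajectory(duplex21, frames)
        present, series = nd.hbond_series(
            traj, "chain I and resid 5 and name C3'",
            "chain I and resid 6 and name C3'", crit)
        np.testing.assert_array_equal(present, dists <= 3.5)
        np.testing.assert_allclose(series.values, dists / 10.0, atol=1e-12)

    def test_multi_atom_selection_rejected(self, duplex21):
        traj = nd.Trajectory(duplex21, [duplex21.coords()])
        with pytest.raises(AnchorError):
            nd.hbond_series(traj, "chain I", "chain J")

    def test_criteria_validation(self):
        with pytest.raises(ValueError):
            nd.HBondCriteria(max_DA_distance=-1)
        with pytest.raises(ValueError):
            nd.HBondCriteria(max_H_angle_dev=120)


class TestRMSD:
    def test_identical_zero(self, duplex21):
        assert nd.rmsd_to_reference(duplex21, None, duplex21) < 1e-9

    def test_translated_with_superpose(self, duplex21):
        f = duplex21.coords() + [3.0, -7.0, 1.0]
        assert nd.rmsd_to_reference(duplex21, f, duplex21,
                                    superpose=True) < 1e-6

    def test_one_atom_displacement_closed_form(self, duplex21):
        f = duplex21.coords()
        d = 4.0
        f[0] = f[0] + [d, 0, 0]
        n = len(f)
        expected = d / np.sqrt(n) / 10.0
        got = nd.rmsd_to_reference(duplex21, f, duplex21, superpose=False)
        assert got == pytest.approx(expected, rel=1e-9)

    def test_superposed_leq_raw(self, ssb_duplex):
        model, site = ssb_duplex
        traj, _ = nd.make_trajectory(
            model, [nd.DeformationSignal("dg", np.linspace(1.2, 2.0, 10),
                                         site=site, noise_sigma=0.05)], seed=9)
        for f in traj.frames:
            raw = nd.rmsd_to_reference(model, f, model, superpose=False)
            sup = nd.rmsd_to_reference(model, f, model, superpose=True)
            assert sup <= raw + 1e-12

    def test_count_mismatch_rejected(self, duplex21):
        with pytest.raises(AnchorError):
            nd.rmsd_to_reference(duplex21, duplex21.coords()[:-1], duplex21)


class TestRigidMotionInvariance:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_all_observables(self, ssb_duplex, seed):
        model, site = ssb_duplex
        rng = np.random.default_rng(seed)
        Q = random_rotation(rng)
        t = rng.normal(scale=30.0, size=3)
        f0 = model.coords()
        f1 = f0 @ Q.T + t
        assert nd.gap_distance(model, f1, site) == pytest.approx(
            nd.gap_distance(model, f0, site), abs=1e-9)
        assert nd.local_twist(model, f1, site) == pytest.approx(
            nd.local_twist(model, f0, site), abs=1e-9)
        a = nd.select(model, "chain I and resid 5")
        b = nd.select(model, "chain J and resid 5")
        for mode in ("min", "com"):
            assert nd.pair_distance(model, f1, a, b, mode) == pytest.approx(
                nd.pair_distance(model, f0, a, b, mode), abs=1e-9)

    def test_dihedral_sign_flips_under_reflection(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(4, 3))
        phi = dihedral_deg(*pts)
        mirrored = pts * [1, 1, -1]
        assert dihedral_deg(*mirrored) == pytest.approx(-phi)


class TestSeriesStats:
    def test_constant_series_single_bin(self):
        s = nd.ObservableSeries("dg", np.full(50, 1.5), "nm")
        st_ = series_stats(s, bins=10)
        mass = st_["histogram"]["mass"]
        assert mass.sum() == pytest.approx(1.0)
        assert (mass > 0).sum() == 1

    def test_uniform_series_flat(self):
        rng = np.random.default_rng(0)
        s = nd.ObservableSeries("dg", rng.uniform(0, 1, 40_000), "nm")
        st_ = series_stats(s, bins=10)
        mass = st_["histogram"]["mass"]
        assert mass.sum() == pytest.approx(1.0)
        # multinomial error: 3 sigma around 0.1 at n = 40000
        sigma = np.sqrt(0.1 * 0.9 / 40_000)
        assert np.abs(mass - 0.1).max() < 4 * sigma

    @given(st.lists(st.floats(-100, 100), min_size=1, max_size=200))
    @settings(deadline=None, max_examples=40)
    def test_mass_always_one(self, values):
        s = nd.ObservableSeries("x", np.array(values), "nm")
        st_ = series_stats(s, bins=7)
        assert st_["histogram"]["mass"].sum() == pytest.approx(1.0)

    def test_empty_rejected(self):
        s = nd.ObservableSeries("x", np.array([]), "nm")
        with pytest.raises(ValueError):
            series_stats(s)


class TestCorrelate:
    def test_exact_line(self):
        x = nd.ObservableSeries("dg", np.arange(10.0), "nm")
        y = nd.ObservableSeries("phi", 2 * np.arange(10.0), "degrees")
        res = correlate(x, y)
        assert res["slope"] == pytest.approx(2.0)
        assert res["r"] == pytest.approx(1.0)

    def test_anticorrelated(self):
        x = nd.ObservableSeries("dg", np.arange(10.0), "nm")
        y = nd.ObservableSeries("phi", -np.arange(10.0), "degrees")
        assert correlate(x, y)["r"] == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        x = nd.ObservableSeries("dg", np.ones(5), "nm")
        y = nd.ObservableSeries("phi", np.arange(5.0), "degrees")
        with pytest.raises(ZeroDivisionError):
            correlate(x, y)

    def test_coupled_injection_recovery(self, ssb_duplex):
        # phi = a * dg + b with noise; recovered within 2 standard errors
        model, site = ssb_duplex
        a_true, b_true = 40.0, 15.0
        rng = np.random.default_rng(12)
        dg_sched = np.linspace(1.2, 2.0, 120)
        phi_sched = a_true * dg_sched + b_true + rng.normal(0, 1.0, 120)
        traj, _ = nd.make_trajectory(
            model,
            [nd.DeformationSignal("phi", phi_sched, site=site),
             nd.DeformationSignal("dg", dg_sched, site=site)],
            seed=3)
        sx = nd.gap_distance_series(traj, site)
        sy = nd.local_twist_series(traj, site)
        res = correlate(sx, sy)
        assert abs(res["slope"] - a_true) < 2 * res["stderr"] + 1e-9
        assert abs(res["intercept"] - b_true) < 2 * res["intercept_stderr"] + 1e-9
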