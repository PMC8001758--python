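"""RDF estimator, reversible-work conversion, shell and barrier extraction."""

from __future__ import annotations

import numpy as np
import pytest

from bilayerlab.constants import KB_KJ_PER_MOL_K
from bilayerlab.pair_structure import (
    PMFProfile,
    RDFResult,
    barriers,
    locate_shells,
    pmf_from_rdf,
    rdf,
)
from bilayerlab.trajectory_io import Trajectory


def _traj(coords, box_edge, labels=None, groups=None):
    coords = np.asarray(coords, dtype=float)
    n_frames, n_particles = coords.shape[:2]
    return Trajectory(
        times=np.arange(n_frames, dtype=float),
        coords=coords,
        box=np.full((n_frames, 3), float(box_edge)),
        labels=labels or ["A"] * n_particles,
        groups=groups or {"A": np.arange(n_particles)},
    )


@pytest.fixture(scope="module")
def ideal_gas():
    rng = np.random.default_rng(7)
    coords = rng.uniform(0, 5.0, size=(40, 500, 3))
    return _traj(coords, 5.0)


class TestRDF:
    def test_ideal_gas_is_flat(self, ideal_gas):
        res = rdf(ideal_gas, "A", "A", r_max=2.0, dr=0.05)
        sel = res.r > 2 * res.dr
        assert np.all(res.g[sel] > 0.9) and np.all(res.g[sel] < 1.1)
        assert 0.95 < res.g[sel].mean() < 1.05

    def test_two_fixed_particles_single_bin(self):
        coords = np.array([[[0.0, 0.0, 0.0], [0.30, 0.0, 0.0]]])
        t = _traj(
            coords, 50.0, labels=["A", "B"],
            groups={"g1": np.array([0]), "g2": np.array([1])},
        )
        res = rdf(t, "g1", "g2", r_max=1.0, dr=0.02)
        nz = np.nonzero(res.counts)[0]
        assert len(nz) == 1
        lo, hi = res.bin_edges[nz[0]], res.bin_edges[nz[0] + 1]
        assert lo <= 0.30 < hi

    def test_bins_below_minimum_distance_are_exactly_zero(self, flat_bilayer):
        res = rdf(flat_bilayer, "P_upper", "P_upper", r_max=2.0, dr=0.05)
        below = res.r < 0.78 - res.dr
        assert np.all(res.g[below] == 0.0)

    def test_r_max_beyond_half_box_rejected(self, ideal_gas):
        with pytest.raises(ValueError, match="half"):
            rdf(ideal_gas, "A", "A", r_max=3.0)

    def test_translation_and_frame_order_invariance(self, ideal_gas):
        res = rdf(ideal_gas, "A", "A", r_max=1.5, dr=0.05)
        shifted = Trajectory(
            times=ideal_gas.times,
            coords=ideal_gas.coords + np.array([1.3, -2.1, 0.7]),
            box=ideal_gas.box,
            labels=ideal_gas.labels,
            groups=ideal_gas.groups,
        )
        res2 = rdf(shifted, "A", "A", r_max=1.5, dr=0.05)
        np.testing.assert_allclose(res.g, res2.g, rtol=1e-10)
        reversed_traj = Trajectory(
            times=ideal_gas.times,
            coords=ideal_gas.coords[::-1],
            box=ideal_gas.box,
            labels=ideal_gas.labels,
            groups=ideal_gas.groups,
        )
        res3 = rdf(reversed_traj, "A", "A", r_max=1.5, dr=0.05)
        np.testing.assert_allclose(res.g, res3.g, rtol=1e-10)

    def test_cross_check_against_mdanalysis_interrdf(self):
        mda = pytest.importorskip("MDAnalysis")
        from MDAnalysis.analysis.rdf import InterRDF

        rng = np.random.default_rng(3)
        coords = rng.uniform(0, 4.0, size=(5, 120, 3))
        t = _traj(coords, 4.0)
        ours = rdf(t, "A", "A", r_max=1.5, dr=0.05)

        u = mda.Universe.empty(120, trajectory=True)
        from MDAnalysis.coordinates.memory import MemoryReader

        u.load_new(coords * 10.0, format=MemoryReader)  # angstrom
        u.dimensions = [40.0, 40.0, 40.0, 90.0, 90.0, 90.0]
        for ts in u.trajectory:
            ts.dimensions = [40.0, 40.0, 40.0, 90.0, 90.0, 90.0]
        ref = InterRDF(u.atoms, u.atoms, nbins=30, range=(1e-6, 15.0), exclusion_block=(1, 1))
        ref.run()
        np.testing.assert_allclose(ours.g[1:], ref.results.rdf[1:], rtol=0.05, atol=0.02)


class TestPMF:
    def _rdf_from_g(self, g, dr=0.01):
        g = np.asarray(g, dtype=float)
        edges = np.arange(len(g) + 1) * dr
        return RDFResult(
            bin_edges=edges, g=g, counts=np.zeros(len(g), dtype=int),
            pair=("a", "b"), n_frames=1, dr=dr,
        )

    def test_unit_g_gives_zero_work(self):
        prof = pmf_from_rdf(self._rdf_from_g(np.ones(50)), temperature=300.0)
        np.testing.assert_allclose(prof.W, 0.0, atol=1e-12)

    def test_one_over_e_bin_costs_exactly_kt(self):
        g = np.ones(10)
        g[4] = np.exp(-1.0)
        prof = pmf_from_rdf(self._rdf_from_g(g), temperature=323.15)
        kt = KB_KJ_PER_MOL_K * 323.15
        assert prof.W[4] == pytest.approx(kt)
        assert kt == pytest.approx(2.7, abs=0.05)

    def test_roundtrip_recovers_g_to_machine_precision(self):
        rng = np.random.default_rng(11)
        g = np.abs(rng.normal(1.0, 0.5, size=200))
        g[rng.integers(0, 200, 10)] = 0.0
        res = self._rdf_from_g(g)
        prof = pmf_from_rdf(res, temperature=323.15)
        kt = KB_KJ_PER_MOL_K * 323.15
        back = np.exp(-prof.W[~prof.mask] / kt)
        np.testing.assert_allclose(back, g[~prof.mask], rtol=1e-13)
        assert np.all(np.isfinite(prof.W))

    def test_kt_unit_option(self):
        g = np.ones(10)
        g[4] = np.exp(-2.0)
        prof = pmf_from_rdf(self._rdf_from_g(g), temperature=310.0, in_kt=True)
        assert prof.W[4] == pytest.approx(2.0)


class TestLocateShells:
    def _rdf_from_g(self, g, dr=0.01):
        g = np.asarray(g, dtype=float)
        edges = np.arange(len(g) + 1) * dr
        return RDFResult(
            bin_edges=edges, g=g, counts=np.zeros(len(g), dtype=int),
            pair=("a", "b"), n_frames=1, dr=dr,
        )

    def test_single_gaussian_peak_located(self):
        r = np.arange(0.005, 0.4, 0.01)
        g = 1.0 + 2.0 * np.exp(-((r - 0.19) ** 2) / (2 * 0.02**2))
        res = self._rdf_from_g(g)
        ext = locate_shells(res)
        peaks = [e for e in ext if e.kind == "max"]
        assert len(peaks) == 1
        assert abs(peaks[0].r - 0.19) <= 0.01

    def test_monotone_profile_has_no_interior_maxima(self):
        g = np.linspace(0.0, 1.0, 50)
        ext = locate_shells(self._rdf_from_g(g))
        assert [e for e in ext if e.kind == "max"] == []

    def test_two_peak_order_matches_brute_force_scan(self):
        r = np.arange(0.005, 0.6, 0.01)
        g = (
            1.0
            + 2.0 * np.exp(-((r - 0.18) ** 2) / (2 * 0.02**2))
            + 1.2 * np.exp(-((r - 0.35) ** 2) / (2 * 0.03**2))
        )
        ext = locate_shells(self._rdf_from_g(g))
        kinds = [e.kind for e in ext]
        assert kinds == ["max", "min", "max"]
        # independent brute-force neighbour scan
        brute = []
        for i in range(1, len(g) - 1):
            if g[i] > g[i - 1] and g[i] >= g[i + 1]:
                brute.append(("max", i))
            elif g[i] < g[i - 1] and g[i] <= g[i + 1]:
                brute.append(("min", i))
        assert [(e.kind, round(e.r, 6)) for e in ext] == [
            (k, round(0.005 + i * 0.01, 6)) for k, i in brute
        ]


class TestBarriers:
    def _profile(self, r, w, temperature=323.15):
        w = np.asarray(w, dtype=float)
        prof = PMFProfile(
            r=np.asarray(r, dtype=float), W=w, mask=np.zeros(len(w), dtype=bool),
            temperature=temperature,
        )
        return prof

    def test_constructed_min_max_pair(self):
        """W with min -5.0 at 0.175 nm and max +6.29 at 0.245 nm -> 11.29."""
        r = np.arange(0.005, 0.4, 0.01)
        w = np.zeros_like(r)
        i_min = np.argmin(np.abs(r - 0.175))
        i_max = np.argmin(np.abs(r - 0.245))
        w[i_min] = -5.0
        w[i_max] = 6.29
        # smooth ramps so the two extrema are the only interior ones
        w = np.interp(r, [r[0], r[i_min], r[i_max], r[-1]], [0.0, -5.0, 6.29, 0.0])
        out = barriers(self._profile(r, w))
        assert len(out) == 1
        b = out[0]
        assert b.delta_f == pytest.approx(11.29)
        assert b.r_min < b.r_max

    def test_monotone_profile_has_no_barriers(self):
        r = np.arange(0.005, 0.4, 0.01)
        assert barriers(self._profile(r, np.linspace(3, -3, len(r)))) == []

    def test_random_piecewise_profile_matches_exhaustive_scan(self):
        rng = np.random.default_rng(5)
        r = np.arange(0.005, 1.0, 0.01)
        w = rng.normal(0.0, 2.0, size=len(r))
        out = barriers(self._profile(r, w))
        # exhaustive: for every interior minimum, the next interior maximum
        ext = []
        for i in range(1, len(w) - 1):
            if w[i] > w[i - 1] and w[i] >= w[i + 1]:
                ext.append(("max", i))
            elif w[i] < w[i - 1] and w[i] <= w[i + 1]:
                ext.append(("min", i))
        expected = []
        for k, (kind, i) in enumerate(ext):
            if kind != "min":
                continue
            nxt = next((j for kk, j in ext[k + 1 :] if kk == "max"), None)
            if nxt is not None:
                expected.append((w[nxt] - w[i], r[i], r[nxt]))
        assert len(out) == len(expected)
        for b, (df, rmin, rmax) in zip(out, expected):
            assert b.delta_f == pytest.approx(df)
            assert b.r_min == pytest.approx(rmin)
            assert b.r_max == pytest.approx(rmax)


class TestDiluteLimit:
    def test_pmf_approaches_pair_potential_at_low_density(self):
        """Exact two-particle Boltzmann sampling: W(r) -> u(r) + const.

        Pairs are drawn with separation r from p(r) proportional to
        4 pi r^2 exp(-u(r)/kBT) by rejection sampling, the dilute
        (two-particle) limit in which the reversible-work theorem is exact.
        """
        kt = KB_KJ_PER_MOL_K * 300.0
        depth, r0, width = 5.0, 0.3, 0.05

        def u(r):
            return -depth * np.exp(-((r - r0) ** 2) / (2 * width**2))

        rng = np.random.default_rng(21)
        n_pairs = 40_000
        r_lo, r_hi = 0.1, 0.8
        rs = []
        while len(rs) < n_pairs:
            cand = rng.uniform(r_lo, r_hi, size=10_000)
            # envelope: max of r^2 exp(-u/kt) over the range
            weight = cand**2 * np.exp(-u(cand) / kt)
            wmax = (r_hi**2) * np.exp(depth / kt)
            keep = rng.uniform(0, wmax, size=10_000) < weight
            rs.extend(cand[keep].tolist())
        rs = np.array(rs[:n_pairs])
        box = 12.0
        centers = rng.uniform(3.0, box - 3.0, size=(n_pairs, 3))
        direction = rng.normal(size=(n_pairs, 3))
        direction /= np.linalg.norm(direction, axis=1, keepdims=True)
        coords = np.stack([centers, centers + rs[:, None] * direction], axis=1)
        t = _traj(
            coords, box, labels=["A", "B"],
            groups={"g1": np.array([0]), "g2": np.array([1])},
        )
        res = rdf(t, "g1", "g2", r_max=1.0, dr=0.02)
        prof = pmf_from_rdf(res, temperature=300.0)
        sel = (prof.r > 0.15) & (prof.r < 0.6) & ~prof.mask
        resid = prof.W[sel] - u(prof.r[sel])
        resid -= resid.mean()
        assert np.abs(resid).max() < 0.5  # kJ/mol, ~0.2 kBT
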