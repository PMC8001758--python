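"""Analytic CV-space potentials with exact gradients.

These potentials play the role of the ground-truth free-energy landscape in
the synthetic study: for overdamped dynamics on one or two collective
variables at fixed temperature, the free energy along the CVs *is* the
potential (up to an additive constant), so every sampler and free-energy
estimator in the package can be validated against a closed form.

Conventions: coordinates are CV vectors; non-periodic CVs are in nm,
periodic ones in degrees with the stated period (360 by default); energies
in kJ/mol, gradients in kJ/mol per CV unit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Potential",
    "Harmonic1D",
    "DoubleWell1D",
    "Flat",
    "GaussianMixture",
    "four_basin_membrane_preset",
]


def _wrap_delta(delta: np.ndarray, period: float) -> np.ndarray:
    """Minimum-image difference for a periodic coordinate."""
    return delta - period * np.round(delta / period)


@dataclass(frozen=True)
class Potential:
    """Base class: a potential over an n-CV box-shaped domain."""

    domain: tuple[tuple[float, float], ...] = ()
    periodic: tuple[bool, ...] = ()
    periods: tuple[float, ...] = ()

    @property
    def n_cv(self) -> int:
        return len(self.domain)

    def energy(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def gradient(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def _atleast_2d(self, x) -> tuple[np.ndarray, bool]:
        x = np.asarray(x, dtype=float)
        single = x.ndim == 1
        return (x[None, :] if single else x), single

    def check_in_domain(self, points: np.ndarray) -> None:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        for j, (lo, hi) in enumerate(self.domain):
            if self.periodic[j]:
                continue
            col = pts[:, j]
            if col.min() < lo - 1e-9 or col.max() > hi + 1e-9:
                raise ValueError(
                    f"coordinate {j} outside declared domain [{lo}, {hi}]"
                )


@dataclass(frozen=True)
class Harmonic1D(Potential):
    """U(z) = k/2 (z - center)^2, k in kJ/mol/nm^2."""

    k: float = 100.0
    center: float = 0.0

    def __post_init__(self):
        if not self.domain:
            object.__setattr__(self, "domain", ((-5.0, 5.0),))
        object.__setattr__(self, "periodic", (False,))
        object.__setattr__(self, "periods", (0.0,))

    def energy(self, x):
        pts, single = self._atleast_2d(x)
        u = 0.5 * self.k * (pts[:, 0] - self.center) ** 2
        return float(u[0]) if single else u

    def gradient(self, x):
        pts, single = self._atleast_2d(x)
        g = self.k * (pts[:, 0:1] - self.center)
        return g[0] if single else g


@dataclass(frozen=True)
class DoubleWell1D(Potential):
    """Quartic double well U(z) = barrier * ((z/a)^2 - 1)^2.

    Minima at z = +/-a with U=0, central barrier of height ``barrier`` at
    z=0; the standard two-state toy landscape.
    """

    barrier: float = 15.0
    a: float = 1.0

    def __post_init__(self):
        if not self.domain:
            object.__setattr__(self, "domain", ((-2.0 * self.a, 2.0 * self.a),))
        object.__setattr__(self, "periodic", (False,))
        object.__setattr__(self, "periods", (0.0,))

    def energy(self, x):
        pts, single = self._atleast_2d(x)
        u = self.barrier * ((pts[:, 0] / self.a) ** 2 - 1.0) ** 2
        return float(u[0]) if single else u

    def gradient(self, x):
        pts, single = self._atleast_2d(x)
        z = pts[:, 0:1]
        g = self.barrier * 4.0 * z * (z**2 - self.a**2) / self.a**4
        return g[0] if single else g


@dataclass(frozen=True)
class Flat(Potential):
    """Zero potential; the flat-landscape limit for sampler calibration."""

    def __post_init__(self):
        if not self.domain:
            object.__setattr__(self, "domain", ((-180.0, 180.0),))
        if not self.periodic:
            object.__setattr__(self, "periodic", tuple(False for _ in self.domain))
        if not self.periods:
            object.__setattr__(self, "periods", tuple(0.0 for _ in self.domain))

    def energy(self, x):
        pts, single = self._atleast_2d(x)
        u = np.zeros(pts.shape[0])
        return 0.0 if single else u

    def gradient(self, x):
        pts, single = self._atleast_2d(x)
        g = np.zeros_like(pts)
        return g[0] if single else g


@dataclass(frozen=True)
class GaussianMixture(Potential):
    """Sum of (signed) Gaussian wells and ridges over the CV domain.

    ``amplitudes[k] < 0`` digs a well, ``> 0`` raises a barrier.  A sigma of
    ``inf`` along one CV makes that term independent of it (a ridge running
    across the whole axis).  Periodic CVs use minimum-image displacements,
    valid while sigma is small against the period.
    """

    amplitudes: tuple[float, ...] = ()
    centers: tuple[tuple[float, ...], ...] = ()
    sigmas: tuple[tuple[float, ...], ...] = ()

    def __post_init__(self):
        if not (len(self.amplitudes) == len(self.centers) == len(self.sigmas)):
            raise ValueError("amplitudes, centers and sigmas must align")
        if not self.periodic:
            object.__setattr__(self, "periodic", tuple(False for _ in self.domain))
        if not self.periods:
            object.__setattr__(self, "periods", tuple(0.0 for _ in self.domain))

    def _terms(self, pts: np.ndarray):
        """Yield (amplitude, gaussian factor, displacement/sigma^2) per term."""
        for amp, c, s in zip(self.amplitudes, self.centers, self.sigmas):
            d = pts - np.asarray(c)
            for j, per in enumerate(self.periodic):
                if per:
                    d[:, j] = _wrap_delta(d[:, j], self.periods[j])
            s = np.asarray(s, dtype=float)
            expo = np.zeros(pts.shape[0])
            dscale = np.zeros_like(pts)
            for j in range(pts.shape[1]):
                if np.isfinite(s[j]):
                    expo += d[:, j] ** 2 / (2.0 * s[j] ** 2)
                    dscale[:, j] = d[:, j] / s[j] ** 2
            yield amp, np.exp(-expo), dscale

    def energy(self, x):
        pts, single = self._atleast_2d(x)
        u = np.zeros(pts.shape[0])
        for amp, gauss, _ in self._terms(pts.copy()):
            u += amp * gauss
        return float(u[0]) if single else u

    def gradient(self, x):
        pts, single = self._atleast_2d(x)
        g = np.zeros_like(pts)
        for amp, gauss, dscale in self._terms(pts.copy()):
            g += -amp * gauss[:, None] * dscale
        return g[0] if single else g


def four_basin_membrane_preset(
    well_depth: float = 20.0,
    ridge_height: float = 45.0,
    z_min: float = 1.5,
) -> GaussianMixture:
    """Toy membrane-insertion landscape over (z [nm], psi [deg], periodic).

    Four Gaussian basins mimic the stable states of an amphiphilic probe at a
    bilayer interface: on each side of the membrane (z = +/-``z_min``) one
    "folded" basin near psi = +/-70 deg and one "extended" basin near
    psi = 180 deg, plus a broad repulsive ridge at the membrane centre (z=0)
    of height ``ridge_height`` that is independent of psi.  All depths are
    package-chosen toy values; the topology, not the chemistry, is the point.
    """
    wells = [
        (+z_min, 70.0),
        (+z_min, 180.0),
        (-z_min, -70.0),
        (-z_min, 180.0),
    ]
    amplitudes = tuple([-well_depth] * 4 + [ridge_height])
    centers = tuple([(z, p) for z, p in wells] + [(0.0, 0.0)])
    sigmas = tuple([(0.35, 25.0)] * 4 + [(0.45, np.inf)])
    return GaussianMixture(
        domain=((-3.0, 3.0), (-180.0, 180.0)),
        periodic=(False, True),
        periods=(0.0, 360.0),
        amplitudes=amplitudes,
        centers=centers,
        sigmas=sigmas,
    )
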