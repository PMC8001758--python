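"""Synthetic study systems with known ground truth.

Three generators stand in for the expensive all-atom simulations that the
analysis layer is designed for:

* a pseudo-bilayer of phosphate marker sites on jittered lattices, whose
  area per lipid and thickness are known by construction;
* an overdamped Langevin probe moving on an analytic CV-space potential,
  whose stationary law is the Boltzmann distribution of that potential;
* a 2D Brownian walker with a prescribed diffusion coefficient.

Every generator is a pure function of (spec, seed): the same spec always
yields the same trajectory.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constants import CM2_PER_S_TO_NM2_PER_PS, KB_KJ_PER_MOL_K
from .potentials import Potential
from .trajectory_io import CVMeta, CVSeries, Trajectory

__all__ = [
    "ToySystemSpec",
    "BilayerSpec",
    "generate_bilayer",
    "simulate_langevin",
    "simulate_brownian2d",
    "ground_truth_fes",
]


@dataclass(frozen=True)
class ToySystemSpec:
    """Overdamped Langevin system on an analytic CV potential.

    Parameters
    ----------
    potential : analytic potential with exact gradient (defines the CVs).
    temperature : K.
    friction : friction coefficient per CV, 1/ps; a scalar applies to all
        CVs.  The per-CV diffusion constant is kB*T/friction in (CV unit)^2/ps.
    dt : integrator time step, ps.
    n_steps : number of integration steps.
    seed : RNG seed; mandatory, there is no global random state.
    x0 : optional start point (defaults to the domain centre).
    sample_stride : record every this-many steps into the output series.
    """

    potential: Potential
    temperature: float = 303.15
    friction: float | tuple[float, ...] = 1.0
    dt: float = 0.01
    n_steps: int = 100_000
    seed: int = 0
    x0: tuple[float, ...] | None = None
    sample_stride: int = 1

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        fr = self.friction_vector()
        if np.any(fr <= 0):
            raise ValueError("friction must be positive")
        if self.n_steps < 1:
            raise ValueError("n_steps must be at least 1")
        if self.sample_stride < 1:
            raise ValueError("sample_stride must be at least 1")

    def friction_vector(self) -> np.ndarray:
        fr = np.asarray(self.friction, dtype=float)
        if fr.ndim == 0:
            fr = np.full(self.potential.n_cv, float(fr))
        if fr.shape != (self.potential.n_cv,):
            raise ValueError("friction must be scalar or one value per CV")
        return fr

    def kt(self) -> float:
        return KB_KJ_PER_MOL_K * self.temperature

    def diffusion_vector(self) -> np.ndarray:
        """Per-CV diffusion constants kB*T/friction in (CV unit)^2/ps."""
        return self.kt() / self.friction_vector()

    def cv_meta(self) -> list[CVMeta]:
        meta = []
        for j in range(self.potential.n_cv):
            periodic = self.potential.periodic[j]
            meta.append(
                CVMeta(
                    name=("psi" if periodic else "z") if self.potential.n_cv <= 2 else f"cv{j+1}",
                    unit="degrees" if periodic else "nm",
                    periodic=periodic,
                    period=self.potential.periods[j] if periodic else 0.0,
                )
            )
        # disambiguate duplicated names (e.g. two non-periodic CVs)
        names = [m.name for m in meta]
        if len(set(names)) != len(names):
            meta = [
                CVMeta(name=f"cv{j+1}", unit=m.unit, periodic=m.periodic, period=m.period)
                for j, m in enumerate(meta)
            ]
        return meta

    def start_point(self) -> np.ndarray:
        if self.x0 is not None:
            x = np.asarray(self.x0, dtype=float)
            if x.shape != (self.potential.n_cv,):
                raise ValueError("x0 arity must match the potential")
            return x.copy()
        return np.array([(lo + hi) / 2.0 for lo, hi in self.potential.domain])


@dataclass(frozen=True)
class BilayerSpec:
    """Pseudo-bilayer of phosphate marker sites on two jittered lattices.

    Each leaflet holds ``n_lipids_per_leaflet`` lipid markers (label ``P``)
    and ``n_chol_per_leaflet`` cholesterol markers (label ``CHL``) on a
    square lattice of the given spacing, at z = +/- leaflet_separation/2.
    Per-frame Gaussian jitter is applied to every site and to the lateral
    box edges, so consecutive frames are independent draws about the lattice.
    """

    n_lipids_per_leaflet: int = 100
    n_chol_per_leaflet: int = 0
    lattice_spacing: float = 0.78
    leaflet_separation: float = 4.0
    positional_jitter_sd: float = 0.0
    box_fluctuation_sd: float = 0.0
    n_frames: int = 1
    seed: int = 0
    frame_dt: float = 1.0
    probe_z: float | None = None

    def __post_init__(self):
        if self.n_lipids_per_leaflet < 1:
            raise ValueError("need at least one lipid per leaflet")
        if self.n_chol_per_leaflet < 0:
            raise ValueError("cholesterol count cannot be negative")
        if self.lattice_spacing <= 0 or self.leaflet_separation <= 0:
            raise ValueError("spacings must be positive")
        if self.positional_jitter_sd >= self.lattice_spacing / 2.0:
            raise ValueError(
                "positional jitter must stay below half the lattice spacing "
                "(leaflet identity would become ambiguous)"
            )
        if self.n_frames < 1:
            raise ValueError("need at least one frame")

    @property
    def sites_per_leaflet(self) -> int:
        return self.n_lipids_per_leaflet + self.n_chol_per_leaflet

    @property
    def lattice_side(self) -> int:
        return int(math.ceil(math.sqrt(self.sites_per_leaflet)))

    @property
    def box_xy(self) -> float:
        return self.lattice_spacing * self.lattice_side


def generate_bilayer(spec: BilayerSpec) -> Trajectory:
    """Generate a two-leaflet marker trajectory from a :class:`BilayerSpec`."""
    rng = np.random.default_rng(spec.seed)
    n_leaf = spec.sites_per_leaflet
    side = spec.lattice_side
    l_box = spec.box_xy

    # lattice points, first n_leaf of side^2, cell-centred
    ii, jj = np.meshgrid(np.arange(side), np.arange(side), indexing="ij")
    lattice_xy = (np.stack([ii.ravel(), jj.ravel()], axis=1)[:n_leaf] + 0.5) * spec.lattice_spacing

    half = spec.leaflet_separation / 2.0
    base = np.zeros((2 * n_leaf, 3))
    base[:n_leaf, :2] = lattice_xy
    base[:n_leaf, 2] = +half
    base[n_leaf:, :2] = lattice_xy
    base[n_leaf:, 2] = -half

    labels = []
    for _leaflet in range(2):
        labels += ["P"] * spec.n_lipids_per_leaflet + ["CHL"] * spec.n_chol_per_leaflet

    n_particles = 2 * n_leaf + (1 if spec.probe_z is not None else 0)
    coords = np.empty((spec.n_frames, n_particles, 3))
    box = np.empty((spec.n_frames, 3))
    lz = max(2.0 * spec.leaflet_separation, spec.leaflet_separation + 2.0)
    for f in range(spec.n_frames):
        jitter = (
            rng.normal(0.0, spec.positional_jitter_sd, size=base.shape)
            if spec.positional_jitter_sd > 0
            else 0.0
        )
        coords[f, : 2 * n_leaf] = base + jitter
        bx = l_box + (rng.normal(0.0, spec.box_fluctuation_sd) if spec.box_fluctuation_sd > 0 else 0.0)
        by = l_box + (rng.normal(0.0, spec.box_fluctuation_sd) if spec.box_fluctuation_sd > 0 else 0.0)
        box[f] = (bx, by, lz)
        if spec.probe_z is not None:
            coords[f, -1] = (bx / 2.0, by / 2.0, spec.probe_z)

    if spec.probe_z is not None:
        labels.append("PRB")

    upper = np.arange(n_leaf)
    lower = np.arange(n_leaf, 2 * n_leaf)
    nl, nc = spec.n_lipids_per_leaflet, spec.n_chol_per_leaflet
    groups = {
        "P_upper": upper[:nl],
        "P_lower": lower[:nl],
        "lipid": np.concatenate([upper[:nl], lower[:nl]]),
        "chol": np.concatenate([upper[nl : nl + nc], lower[nl : nl + nc]]),
    }
    if spec.probe_z is not None:
        groups["probe"] = np.array([n_particles - 1])

    return Trajectory(
        times=np.arange(spec.n_frames) * spec.frame_dt,
        coords=coords,
        box=box,
        labels=labels,
        groups=groups,
    )


# ---------------------------------------------------------------------------
# Langevin sampler
# ---------------------------------------------------------------------------

#: declared stability bound: the Euler-Maruyama drift update must satisfy
#: dt * max|U''| / friction < this, or the harmonic-like relaxation within
#: the stiffest well is integrated inaccurately (and diverges at 2.0)
_STIFFNESS_BOUND = 0.5


def _check_stability(spec: ToySystemSpec) -> None:
    pot = spec.potential
    fr = spec.friction_vector()
    # estimate the maximum curvature per CV from the gradient on a coarse grid
    axes = [np.linspace(lo, hi, 81) for lo, hi in pot.domain]
    mesh = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([m.ravel() for m in mesh], axis=1)
    grad = np.atleast_2d(pot.gradient(pts)).reshape(mesh[0].shape + (pot.n_cv,))
    for j in range(pot.n_cv):
        h = axes[j][1] - axes[j][0]
        curv = float(np.max(np.abs(np.diff(grad[..., j], axis=j)))) / h
        stiffness = spec.dt * curv / fr[j]
        if stiffness > _STIFFNESS_BOUND:
            raise ValueError(
                f"dt={spec.dt} ps is too large for stable integration of CV {j}: "
                f"dt * max|U''| / friction = {stiffness:.3g} exceeds the declared "
                f"bound {_STIFFNESS_BOUND}; reduce dt or increase friction"
            )


def _reflect(x: float, lo: float, hi: float) -> float:
    """Reflect a coordinate back into [lo, hi] (assumes small overshoot)."""
    while x < lo or x > hi:
        if x < lo:
            x = 2.0 * lo - x
        if x > hi:
            x = 2.0 * hi - x
    return x


def simulate_langevin(spec: ToySystemSpec) -> CVSeries:
    """Sample CV space by overdamped (Euler-Maruyama) Langevin dynamics.

    The update per CV j is
    ``x += -grad_j U * dt / friction_j + sqrt(2 kT dt / friction_j) * xi``,
    whose stationary distribution is the Boltzmann law exp(-U/kB T).
    Periodic CVs are wrapped each step; non-periodic CVs reflect at the
    declared domain edges.
    """
    _check_stability(spec)
    pot = spec.potential
    n_cv = pot.n_cv
    rng = np.random.default_rng(spec.seed)
    fr = spec.friction_vector()
    mob_dt = spec.dt / fr
    noise_sd = np.sqrt(2.0 * spec.kt() * spec.dt / fr)
    x = spec.start_point()

    n_samples = spec.n_steps // spec.sample_stride
    out = np.empty((n_samples, n_cv))
    times = (np.arange(1, n_samples + 1) * spec.sample_stride) * spec.dt

    periodic = pot.periodic
    periods = pot.periods
    domain = pot.domain
    k_out = 0
    for step in range(1, spec.n_steps + 1):
        g = pot.gradient(x)
        x = x - g * mob_dt + noise_sd * rng.standard_normal(n_cv)
        for j in range(n_cv):
            if periodic[j]:
                half = periods[j] / 2.0
                x[j] = x[j] - periods[j] * math.floor((x[j] + half) / periods[j])
                if x[j] <= -half:  # keep the (-half, half] convention
                    x[j] += periods[j]
            else:
                x[j] = _reflect(x[j], domain[j][0], domain[j][1])
        if step % spec.sample_stride == 0:
            out[k_out] = x
            k_out += 1

    return CVSeries(times=times, values=out, cv_meta=spec.cv_meta())


def simulate_brownian2d(
    D: float,
    n_steps: int,
    dt: float = 1.0,
    seed: int = 0,
    n_walkers: int = 1,
    box_edge: float = 1000.0,
) -> Trajectory:
    """Free 2D Brownian motion of probe walkers with diffusion constant D.

    Parameters
    ----------
    D : diffusion coefficient in cm^2/s (the unit diffusion tables are
        printed in); internally converted to nm^2/ps.
    n_steps : number of steps; the trajectory has n_steps + 1 frames.
    dt : time step in ps.
    seed : RNG seed.
    n_walkers : independent walkers (all in group "probe"); averaging the
        MSD over walkers shrinks the estimator variance honestly.
    box_edge : box size in nm (the walk is not wrapped; the box is simply
        large enough that observables needing one are well defined).

    The x and y increments are i.i.d. Gaussian with variance 2*D*dt per
    axis, the exact discrete-time law of Brownian motion; z stays at 0.
    """
    if D <= 0:
        raise ValueError("diffusion coefficient must be positive")
    if n_steps < 1:
        raise ValueError("n_steps must be at least 1")
    if dt <= 0:
        raise ValueError("dt must be positive")
    if n_walkers < 1:
        raise ValueError("n_walkers must be at least 1")
    d_nm = D * CM2_PER_S_TO_NM2_PER_PS
    rng = np.random.default_rng(seed)
    steps = rng.normal(0.0, math.sqrt(2.0 * d_nm * dt), size=(n_steps, n_walkers, 2))
    xy = np.concatenate(
        [np.zeros((1, n_walkers, 2)), np.cumsum(steps, axis=0)]
    ) + box_edge / 2.0
    coords = np.zeros((n_steps + 1, n_walkers, 3))
    coords[:, :, :2] = xy
    return Trajectory(
        times=np.arange(n_steps + 1) * dt,
        coords=coords,
        box=np.full((n_steps + 1, 3), box_edge),
        labels=["PRB"] * n_walkers,
        groups={"probe": np.arange(n_walkers)},
    )


def ground_truth_fes(spec: ToySystemSpec, grid: list[np.ndarray]):
    """Exact free-energy surface of a toy spec on the given grid axes.

    For overdamped dynamics on the CVs themselves the free energy equals the
    potential up to a constant, so F(grid) = U(grid) - min U (min-zero
    convention).  Returns a :class:`~bilayerlab.wtm_engine.FES2D`.
    """
    from .wtm_engine import FES2D  # local import avoids a module cycle

    pot = spec.potential
    axes = [np.asarray(a, dtype=float) for a in grid]
    if len(axes) != pot.n_cv:
        raise ValueError("grid arity must match the potential")
    for j, (lo, hi) in enumerate(pot.domain):
        if axes[j].min() < lo - 1e-9 or axes[j].max() > hi + 1e-9:
            raise ValueError(f"grid axis {j} extends outside the potential domain [{lo}, {hi}]")
    mesh = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([m.ravel() for m in mesh], axis=1)
    u = np.asarray(pot.energy(pts)).reshape(mesh[0].shape)
    return FES2D(axes=axes, F=u - u.min(), cv_meta=spec.cv_meta(), convention="min-zero")
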