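"""Well-tempered metadynamics (WTM) on toy CV-space systems.

The engine propagates overdamped Langevin dynamics on an analytic potential
U(s) plus a history-dependent bias V(s, t) built from Gaussian hills.  A
hill deposited at CV point s gets the tempered height

    w = w0 * exp(-V(s) / (kB * dT)),       dT = (gamma - 1) * T,

so the bias converges to (1 - 1/gamma) times the negative free energy and
the free-energy surface is recovered as

    F(s) = -(gamma / (gamma - 1)) * V(s) + C.

The bias and its analytic gradient are accumulated on a CV grid as hills
are deposited, so a propagation step costs a grid interpolation rather than
a sum over the full hill history.  Periodic CVs (the torsion psi) use
minimum-image displacements in hills, grids and paths throughout.

Basins of a reconstructed surface are local minima below a depth threshold;
the barrier from basin i to basin j is the minimax-path saddle: the lowest,
over all grid paths (8-connected, wrapping across periodic axes), of the
highest F along the path, minus F(basin i).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import KB_KJ_PER_MOL_K
from .trajectory_io import CVMeta, CVSeries, HillLog

__all__ = [
    "WTMConfig",
    "FES2D",
    "Basin",
    "FESBarrier",
    "hill_height",
    "deposit_hill",
    "bias_value",
    "run_wtm",
    "reconstruct_fes",
    "convergence_trace",
    "find_basins_barriers",
    "minimax_barrier",
    "default_grid",
]


# ---------------------------------------------------------------------------
# configuration and result types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WTMConfig:
    """Parameters of a well-tempered metadynamics run.

    Defaults follow common membrane-WTM practice: hill width 0.30 nm on the
    distance CV and 20 degrees on the torsion, starting hill 1.0 kJ/mol,
    deposition stride 1 ps, bias factor 10.
    """

    sigma: tuple[float, ...] = (0.30, 20.0)
    w0: float = 1.0                      # starting hill height, kJ/mol
    stride: float = 1.0                  # deposition stride, ps
    bias_factor: float = 10.0            # gamma, dimensionless
    temperature: float | None = None     # K; None = take the system's
    run_length_ns: float | None = None   # None = use the spec's n_steps
    grid_spacing: tuple[float, ...] | None = None  # default 0.05 nm / 2 deg
    colvar_stride: float | None = None   # ps; None = deposition stride

    def __post_init__(self):
        if any(s <= 0 for s in self.sigma):
            raise ValueError("hill widths must be positive")
        if self.w0 <= 0:
            raise ValueError("starting hill height must be positive")
        if self.stride <= 0:
            raise ValueError("deposition stride must be positive")
        if self.bias_factor <= 1:
            raise ValueError("bias factor must exceed 1")

    def delta_t(self, temperature: float) -> float:
        """The tempering temperature offset dT = (gamma - 1) T, in K."""
        return (self.bias_factor - 1.0) * temperature


@dataclass(frozen=True)
class Basin:
    label: str
    location: tuple[float, ...]   # CV coordinates of the minimum
    F: float                      # kJ/mol
    grid_index: tuple[int, ...]


@dataclass(frozen=True)
class FESBarrier:
    """Minimax-path barrier from one basin to another."""

    from_label: str
    to_label: str
    delta_f: float                # F(saddle) - F(from basin), kJ/mol
    saddle_F: float
    saddle_location: tuple[float, ...]


@dataclass
class FES2D:
    """Free-energy surface on a regular CV grid (1D profiles also fit).

    ``convention`` is ``"min-zero"`` (minimum at 0) or ``"max-zero"``
    (surface referenced to its highest value, the convention used when the
    bulk region is taken as the global zero).
    """

    axes: list[np.ndarray]
    F: np.ndarray
    cv_meta: list[CVMeta]
    convention: str = "min-zero"
    basins: list[Basin] = field(default_factory=list)
    barrier_list: list[FESBarrier] = field(default_factory=list)

    def __post_init__(self):
        self.F = np.asarray(self.F, dtype=float)
        shape = tuple(len(a) for a in self.axes)
        if self.F.shape != shape:
            raise ValueError(f"F shape {self.F.shape} does not match axes {shape}")
        if self.convention not in ("min-zero", "max-zero"):
            raise ValueError("convention must be 'min-zero' or 'max-zero'")

    @property
    def periodic_flags(self) -> tuple[bool, ...]:
        return tuple(m.periodic for m in self.cv_meta)


# ---------------------------------------------------------------------------
# hills and bias
# ---------------------------------------------------------------------------


def hill_height(elapsed_bias: float, cfg: WTMConfig, temperature: float) -> float:
    """Tempered hill height w = w0 exp(-V(s)/(kB dT)), dT = (gamma-1) T."""
    if cfg.bias_factor <= 1:
        raise ValueError("bias factor must exceed 1")
    kb_dt = KB_KJ_PER_MOL_K * cfg.delta_t(temperature)
    return cfg.w0 * math.exp(-elapsed_bias / kb_dt)


def deposit_hill(
    log: HillLog | None,
    time: float,
    cv_point,
    elapsed_bias: float,
    cfg: WTMConfig,
    temperature: float,
    cv_meta: list[CVMeta] | None = None,
) -> HillLog:
    """Append one tempered hill at ``cv_point`` and return the extended log.

    ``elapsed_bias`` is the bias V(s) already accumulated at that point; the
    first hill of a run (V = 0) therefore has height exactly w0.
    """
    point = np.asarray(cv_point, dtype=float)
    w = hill_height(elapsed_bias, cfg, temperature)
    sigma = np.asarray(cfg.sigma, dtype=float)
    if sigma.shape != point.shape:
        raise ValueError("cv_point arity must match the configured hill widths")
    if log is None:
        return HillLog(
            deposit_times=np.array([time]),
            centers=point[None, :],
            widths=sigma[None, :],
            heights=np.array([w]),
            bias_factor=cfg.bias_factor,
            cv_meta=cv_meta or [],
        )
    return HillLog(
        deposit_times=np.append(log.deposit_times, time),
        centers=np.vstack([log.centers, point[None, :]]),
        widths=np.vstack([log.widths, sigma[None, :]]),
        heights=np.append(log.heights, w),
        bias_factor=log.bias_factor,
        cv_meta=log.cv_meta,
    )


def _wrapped_delta(delta: np.ndarray, meta: CVMeta) -> np.ndarray:
    if meta.periodic:
        return delta - meta.period * np.round(delta / meta.period)
    return delta


def bias_value(hills: HillLog, cv_point, n_hills: int | None = None) -> float | np.ndarray:
    """Total bias V(s) = sum of deposited Gaussians at one or many points.

    Periodic CVs use minimum-image displacements, so a hill at 179 degrees
    contributes at -179 degrees as if 2 degrees away.  ``n_hills`` restricts
    the sum to the first hills (for convergence checkpoints).
    """
    pts = np.asarray(cv_point, dtype=float)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    if pts.shape[1] != hills.n_cv:
        raise ValueError(
            f"cv_point arity {pts.shape[1]} does not match the hill log ({hills.n_cv} CVs)"
        )
    n = hills.n_hills if n_hills is None else min(n_hills, hills.n_hills)
    out = np.zeros(pts.shape[0])
    # chunk over hills to bound the (points x hills) intermediate
    chunk = max(1, int(4_000_000 // max(pts.shape[0], 1)))
    for k0 in range(0, n, chunk):
        k1 = min(k0 + chunk, n)
        expo = np.zeros((pts.shape[0], k1 - k0))
        for j, meta in enumerate(hills.cv_meta):
            d = pts[:, j, None] - hills.centers[None, k0:k1, j]
            d = _wrapped_delta(d, meta)
            expo += d**2 / (2.0 * hills.widths[None, k0:k1, j] ** 2)
        out += np.exp(-expo) @ hills.heights[k0:k1]
    return float(out[0]) if single else out


# ---------------------------------------------------------------------------
# grids
# ---------------------------------------------------------------------------


def default_grid(potential, cfg: WTMConfig | None = None) -> list[np.ndarray]:
    """Regular grid axes over a potential's CV domain.

    Non-periodic axes span the domain inclusively; periodic axes tile one
    period without duplicating the seam point.  Default spacings: 0.05 nm
    for distance-like CVs, 2 degrees for angular ones.
    """
    spacing = cfg.grid_spacing if cfg is not None and cfg.grid_spacing else None
    axes = []
    for j, (lo, hi) in enumerate(potential.domain):
        if spacing is not None:
            h = spacing[j]
        else:
            h = 2.0 if potential.periodic[j] else 0.05
        if potential.periodic[j]:
            period = potential.periods[j]
            n = int(round(period / h))
            axes.append(-period / 2.0 + np.arange(n) * h)
        else:
            n = int(round((hi - lo) / h))
            axes.append(lo + np.arange(n + 1) * h)
    return axes


class _BiasGrid:
    """Bias potential and its gradient accumulated on a regular CV grid."""

    def __init__(self, axes: list[np.ndarray], cv_meta: list[CVMeta]):
        self.axes = [np.asarray(a, float) for a in axes]
        self.meta = cv_meta
        self.spacing = [float(a[1] - a[0]) for a in self.axes]
        shape = tuple(len(a) for a in self.axes)
        self.V = np.zeros(shape)
        self.G = [np.zeros(shape) for _ in self.axes]

    def add_hill(self, center: np.ndarray, sigma: np.ndarray, height: float) -> None:
        factors = []
        dscaled = []
        for j, axis in enumerate(self.axes):
            d = _wrapped_delta(axis - center[j], self.meta[j])
            factors.append(np.exp(-(d**2) / (2.0 * sigma[j] ** 2)))
            dscaled.append(d / sigma[j] ** 2)
        if len(self.axes) == 1:
            gauss = height * factors[0]
            self.V += gauss
            self.G[0] += gauss * (-dscaled[0])
        else:
            gauss = height * factors[0][:, None] * factors[1][None, :]
            self.V += gauss
            self.G[0] += gauss * (-dscaled[0][:, None])
            self.G[1] += gauss * (-dscaled[1][None, :])

    def _locate(self, x: np.ndarray):
        idx = []
        frac = []
        for j, axis in enumerate(self.axes):
            n = len(axis)
            t = (x[j] - axis[0]) / self.spacing[j]
            if self.meta[j].periodic:
                t = t % n
                i0 = int(t) % n
                i1 = (i0 + 1) % n
            else:
                t = min(max(t, 0.0), n - 1.000001)
                i0 = int(t)
                i1 = i0 + 1
            idx.append((i0, i1))
            frac.append(t - int(t))
        return idx, frac

    def interpolate(self, grid: np.ndarray, x: np.ndarray) -> float:
        """Multilinear interpolation of one accumulated grid at point x."""
        idx, frac = self._locate(x)
        if len(self.axes) == 1:
            (i0, i1), = idx
            f, = frac
            return (1 - f) * grid[i0] + f * grid[i1]
        (i0, i1), (j0, j1) = idx
        fi, fj = frac
        return (
            (1 - fi) * ((1 - fj) * grid[i0, j0] + fj * grid[i0, j1])
            + fi * ((1 - fj) * grid[i1, j0] + fj * grid[i1, j1])
        )

    def value(self, x: np.ndarray) -> float:
        return self.interpolate(self.V, x)

    def gradient(self, x: np.ndarray) -> np.ndarray:
        idx, frac = self._locate(x)
        if len(self.axes) == 1:
            (i0, i1), = idx
            f, = frac
            return np.array([(1 - f) * self.G[0][i0] + f * self.G[0][i1]])
        (i0, i1), (j0, j1) = idx
        fi, fj = frac
        w00 = (1 - fi) * (1 - fj)
        w01 = (1 - fi) * fj
        w10 = fi * (1 - fj)
        w11 = fi * fj
        g0, g1 = self.G
        return np.array(
            [
                w00 * g0[i0, j0] + w01 * g0[i0, j1] + w10 * g0[i1, j0] + w11 * g0[i1, j1],
                w00 * g1[i0, j0] + w01 * g1[i0, j1] + w10 * g1[i1, j0] + w11 * g1[i1, j1],
            ]
        )


# ---------------------------------------------------------------------------
# the engine
# ---------------------------------------------------------------------------


def run_wtm(spec, cfg: WTMConfig, colvar_path=None, hills_path=None):
    """Run well-tempered metadynamics on a toy Langevin system.

    Parameters
    ----------
    spec : :class:`~bilayerlab.toy_system.ToySystemSpec`
        Defines the potential, temperature, friction, time step and seed.
    cfg : :class:`WTMConfig`
        Hill widths, starting height, stride, bias factor, grids.
    colvar_path, hills_path : optional paths
        When given, the CV stream and hill log are also written in the
        COLVAR/HILLS dialect.

    Returns
    -------
    (CVSeries, HillLog)
        The recorded CV trajectory and the deposited hills.

    Notes
    -----
    The bias and its gradient are accumulated on a grid (spacing finer than
    the hill widths) and interpolated multilinearly at the walker position;
    hill heights are tempered with the bias value at the deposit point.
    Identical spec+cfg always reproduce the identical hill log.
    """
    from .toy_system import _check_stability  # shared drift-step bound
    from .trajectory_io import write_colvar, write_hills

    pot = spec.potential
    n_cv = pot.n_cv
    sigma = np.asarray(cfg.sigma[:n_cv], dtype=float)
    if len(cfg.sigma) < n_cv:
        raise ValueError("cfg.sigma must provide one width per CV")
    temperature = cfg.temperature if cfg.temperature is not None else spec.temperature
    if abs(temperature - spec.temperature) > 1e-9:
        raise ValueError(
            "WTMConfig.temperature disagrees with the system temperature; "
            "set one of them to None/equal"
        )
    _check_stability(spec)

    dt = spec.dt
    if cfg.stride < dt:
        raise ValueError("deposition stride must be at least the integrator time step")
    stride_steps = max(1, int(round(cfg.stride / dt)))
    colvar_stride = cfg.colvar_stride if cfg.colvar_stride is not None else cfg.stride
    colvar_steps = max(1, int(round(colvar_stride / dt)))
    if cfg.run_length_ns is not None:
        n_steps = int(round(cfg.run_length_ns * 1000.0 / dt))
    else:
        n_steps = spec.n_steps

    meta = spec.cv_meta()
    grid_axes = default_grid(pot, cfg)
    bias = _BiasGrid(grid_axes, meta)

    # tabulate the (static) potential gradient on the same grid once, so a
    # step costs two interpolations regardless of the potential's complexity
    mesh = np.meshgrid(*grid_axes, indexing="ij")
    pts = np.stack([m.ravel() for m in mesh], axis=1)
    u_grad_flat = np.atleast_2d(pot.gradient(pts))
    u_grid = _BiasGrid(grid_axes, meta)
    for j in range(n_cv):
        u_grid.G[j] = u_grad_flat[:, j].reshape(mesh[0].shape)

    rng = np.random.default_rng(spec.seed)
    fr = spec.friction_vector()
    mob_dt = dt / fr
    noise_sd = np.sqrt(2.0 * spec.kt() * dt / fr)
    kb_dt = KB_KJ_PER_MOL_K * cfg.delta_t(temperature)

    x = spec.start_point()
    periodic = pot.periodic
    periods = pot.periods
    domain = pot.domain

    hill_times, hill_centers, hill_heights = [], [], []
    cv_times, cv_values = [], []

    for step in range(1, n_steps + 1):
        g = u_grid.gradient(x) + bias.gradient(x)
        x = x - g * mob_dt + noise_sd * rng.standard_normal(n_cv)
        if not np.all(np.isfinite(x)):
            raise RuntimeError(
                f"integrator diverged at step {step} (t={step*dt:.3f} ps); "
                "reduce dt or increase friction"
            )
        for j in range(n_cv):
            if periodic[j]:
                half = periods[j] / 2.0
                x[j] -= periods[j] * math.floor((x[j] + half) / periods[j])
                if x[j] <= -half:
                    x[j] += periods[j]
            else:
                lo, hi = domain[j]
                while x[j] < lo or x[j] > hi:
                    if x[j] < lo:
                        x[j] = 2.0 * lo - x[j]
                    if x[j] > hi:
                        x[j] = 2.0 * hi - x[j]
        if step % stride_steps == 0:
            v = bias.value(x)
            w = cfg.w0 * math.exp(-v / kb_dt)
            bias.add_hill(x, sigma, w)
            hill_times.append(step * dt)
            hill_centers.append(x.copy())
            hill_heights.append(w)
        if step % colvar_steps == 0:
            cv_times.append(step * dt)
            cv_values.append(x.copy())

    if not hill_times:
        raise ValueError("run too short: no hills were deposited")
    hills = HillLog(
        deposit_times=np.array(hill_times),
        centers=np.array(hill_centers),
        widths=np.tile(sigma, (len(hill_times), 1)),
        heights=np.array(hill_heights),
        bias_factor=cfg.bias_factor,
        cv_meta=meta,
    )
    series = CVSeries(times=np.array(cv_times), values=np.array(cv_values), cv_meta=meta)
    if colvar_path is not None:
        write_colvar(series, colvar_path)
    if hills_path is not None:
        write_hills(hills, hills_path)
    return series, hills


# ---------------------------------------------------------------------------
# shipped study presets
# ---------------------------------------------------------------------------


def double_well_study(seed: int = 7):
    """Shipped 1D benchmark: quartic double well, 15 kJ/mol barrier.

    Returns (spec, cfg) for a 3 ns tempered run (dt 5 fs, friction 10/ps,
    hill width 0.1 nm, stride 1 ps, bias factor 10 at 303.15 K) that
    converges the two-well surface to well under 1 kBT.
    """
    from .potentials import DoubleWell1D
    from .toy_system import ToySystemSpec

    pot = DoubleWell1D(barrier=15.0, a=1.0)
    spec = ToySystemSpec(
        potential=pot, temperature=303.15, friction=10.0, dt=0.005, n_steps=1, seed=seed
    )
    cfg = WTMConfig(sigma=(0.1,), w0=1.0, stride=1.0, bias_factor=10.0, run_length_ns=3.0)
    return spec, cfg


def four_basin_study(seed: int = 11):
    """Shipped 2D benchmark: four-basin membrane-insertion toy landscape.

    Returns (spec, cfg) for a 20 ns tempered run over (z, psi) with the
    conventional hill widths (0.30 nm, 20 deg), starting hill 1 kJ/mol,
    stride 1 ps and bias factor 10 at 303.15 K.
    """
    from .potentials import four_basin_membrane_preset
    from .toy_system import ToySystemSpec

    pot = four_basin_membrane_preset()
    spec = ToySystemSpec(
        potential=pot,
        temperature=303.15,
        friction=(10.0, 0.05),
        dt=0.01,
        n_steps=1,
        seed=seed,
    )
    cfg = WTMConfig(
        sigma=(0.30, 20.0), w0=1.0, stride=1.0, bias_factor=10.0, run_length_ns=20.0
    )
    return spec, cfg


# ---------------------------------------------------------------------------
# FES reconstruction and analysis
# ---------------------------------------------------------------------------


def reconstruct_fes(
    hills: HillLog,
    grid: list[np.ndarray],
    convention: str = "min-zero",
    n_hills: int | None = None,
) -> FES2D:
    """Free-energy surface from a hill log: F = -(gamma/(gamma-1)) V + C.

    The additive constant C implements the zero convention: ``"min-zero"``
    anchors the global minimum at 0, ``"max-zero"`` the global maximum (the
    bulk-referenced display convention).
    """
    if hills.n_hills == 0:
        raise ValueError("hill log is empty")
    axes = [np.asarray(a, float) for a in grid]
    if len(axes) != hills.n_cv:
        raise ValueError("grid arity must match the hill log")
    n = hills.n_hills if n_hills is None else min(n_hills, hills.n_hills)
    # Gaussians factorise over CV axes, so each hill is an outer product of
    # small per-axis factor vectors — far cheaper than pairwise distances
    shape = tuple(len(a) for a in axes)
    v = np.zeros(shape)
    for k in range(n):
        factors = []
        for j, meta in enumerate(hills.cv_meta):
            d = _wrapped_delta(axes[j] - hills.centers[k, j], meta)
            factors.append(np.exp(-(d**2) / (2.0 * hills.widths[k, j] ** 2)))
        if len(axes) == 1:
            v += hills.heights[k] * factors[0]
        else:
            v += hills.heights[k] * factors[0][:, None] * factors[1][None, :]
    gamma = hills.bias_factor
    f = -(gamma / (gamma - 1.0)) * v
    f = f - (f.max() if convention == "max-zero" else f.min())
    return FES2D(axes=axes, F=f, cv_meta=list(hills.cv_meta), convention=convention)


def _neighbor_offsets(ndim: int) -> list[tuple[int, ...]]:
    offsets = []
    ranges = [(-1, 0, 1)] * ndim
    def rec(prefix):
        if len(prefix) == ndim:
            if any(prefix):
                offsets.append(tuple(prefix))
            return
        for d in ranges[len(prefix)]:
            rec(prefix + [d])
    rec([])
    return offsets


def _neighbors(index: tuple[int, ...], shape: tuple[int, ...], periodic: tuple[bool, ...]):
    for off in _neighbor_offsets(len(shape)):
        nb = []
        ok = True
        for j, (i, d, n) in enumerate(zip(index, off, shape)):
            k = i + d
            if periodic[j]:
                k %= n
            elif k < 0 or k >= n:
                ok = False
                break
            nb.append(k)
        if ok:
            yield tuple(nb)


def _local_minima(F: np.ndarray, periodic: tuple[bool, ...]) -> list[tuple[int, ...]]:
    out = []
    it = np.ndindex(F.shape)
    for idx in it:
        v = F[idx]
        if all(v <= F[nb] for nb in _neighbors(idx, F.shape, periodic)) and any(
            v < F[nb] for nb in _neighbors(idx, F.shape, periodic)
        ):
            out.append(idx)
    return out


class _UnionFind:
    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, a):
        p = self.parent
        while p[a] != a:
            p[a] = p[p[a]]
            a = p[a]
        return a

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra
        return ra


def _watershed_saddles(F: np.ndarray, periodic, basin_indices):
    """Minimax saddle F between every basin pair via flooding in F order.

    Activates grid points from low to high F; when two connected components
    containing different basins merge, the activation value is the minimax
    saddle for every basin pair split across the two components.
    """
    shape = F.shape
    flat = F.ravel()
    order = np.argsort(flat, kind="stable")
    uf = _UnionFind(flat.size)
    basins_of: dict[int, set[int]] = {}
    basin_flat = [int(np.ravel_multi_index(b, shape)) for b in basin_indices]
    basin_rank = {bf: k for k, bf in enumerate(basin_flat)}
    active = np.zeros(flat.size, dtype=bool)
    saddles: dict[tuple[int, int], tuple[float, int]] = {}
    n_pairs_target = len(basin_flat) * (len(basin_flat) - 1) // 2

    for fi in order:
        fi = int(fi)
        idx = np.unravel_index(fi, shape)
        active[fi] = True
        if fi in basin_rank:
            basins_of[uf.find(fi)] = {basin_rank[fi]}
        for nb in _neighbors(idx, shape, periodic):
            nf = int(np.ravel_multi_index(nb, shape))
            if not active[nf]:
                continue
            ra, rb = uf.find(fi), uf.find(nf)
            if ra == rb:
                continue
            sa = basins_of.pop(ra, set())
            sb = basins_of.pop(rb, set())
            for a in sa:
                for b in sb:
                    key = (min(a, b), max(a, b))
                    if key not in saddles:
                        saddles[key] = (float(flat[fi]), fi)
            root = uf.union(ra, rb)
            merged = sa | sb
            if merged:
                basins_of[root] = merged
        if len(saddles) == n_pairs_target and n_pairs_target > 0:
            break
    return saddles


def find_basins_barriers(
    fes: FES2D,
    n_basins_max: int = 6,
    depth_fraction: float = 0.25,
) -> tuple[list[Basin], list[FESBarrier]]:
    """Locate basins and the minimax barriers between every basin pair.

    Basins are the local minima whose F lies within ``depth_fraction`` of
    the surface's total range above the global minimum, the ``n_basins_max``
    deepest kept and labelled A, B, C ... in order of depth.  The barrier
    from basin i to j is the minimax-path saddle height minus F(basin i),
    so it is measured from the departing basin and is not symmetric.

    The results are also stored on ``fes.basins`` / ``fes.barrier_list``.
    """
    if not np.all(np.isfinite(fes.F)):
        raise ValueError("FES contains non-finite values")
    periodic = fes.periodic_flags
    minima = _local_minima(fes.F, periodic)
    if not minima:
        fes.basins, fes.barrier_list = [], []
        return [], []
    f_min, f_max = float(fes.F.min()), float(fes.F.max())
    threshold = f_min + depth_fraction * (f_max - f_min)
    minima = [m for m in minima if fes.F[m] <= threshold]
    minima.sort(key=lambda m: fes.F[m])
    minima = minima[:n_basins_max]
    labels = [chr(ord("A") + k) for k in range(len(minima))]
    basins = [
        Basin(
            label=lab,
            location=tuple(float(fes.axes[j][m[j]]) for j in range(len(fes.axes))),
            F=float(fes.F[m]),
            grid_index=m,
        )
        for lab, m in zip(labels, minima)
    ]
    barriers: list[FESBarrier] = []
    if len(basins) >= 2:
        saddles = _watershed_saddles(fes.F, periodic, [b.grid_index for b in basins])
        for (a, b), (f_saddle, flat_idx) in sorted(saddles.items()):
            loc_idx = np.unravel_index(flat_idx, fes.F.shape)
            loc = tuple(float(fes.axes[j][loc_idx[j]]) for j in range(len(fes.axes)))
            for i, j in ((a, b), (b, a)):
                barriers.append(
                    FESBarrier(
                        from_label=basins[i].label,
                        to_label=basins[j].label,
                        delta_f=float(f_saddle - basins[i].F),
                        saddle_F=float(f_saddle),
                        saddle_location=loc,
                    )
                )
    fes.basins, fes.barrier_list = basins, barriers
    return basins, barriers


def minimax_barrier(
    F: np.ndarray,
    axes: list[np.ndarray],
    periodic: tuple[bool, ...],
    start_index: tuple[int, ...],
    end_index: tuple[int, ...],
) -> float:
    """Minimax saddle height between two fixed grid points.

    The lowest possible value, over all 8-connected grid paths from start to
    end (wrapping across periodic axes), of the maximum F along the path.
    """
    saddles = _watershed_saddles(F, periodic, [start_index, end_index])
    if (0, 1) not in saddles:
        raise ValueError("start and end never connect on the grid")
    return saddles[(0, 1)][0]


def convergence_trace(
    hills: HillLog,
    grid: list[np.ndarray],
    checkpoints,
    n_basins_max: int = 4,
):
    """Basin-pair barriers recomputed from truncated hill logs over time.

    The basins are located once, on the surface reconstructed from the full
    log; at each checkpoint time the surface is rebuilt from the hills
    deposited up to that time and the minimax barrier between every basin
    pair is re-measured at the fixed basin grid points.  Returns a pandas
    DataFrame with columns ``time``, ``from``, ``to``, ``delta_f``.
    """
    import pandas as pd

    checkpoints = sorted(float(c) for c in checkpoints)
    if len(checkpoints) < 2:
        raise ValueError("need at least two checkpoints to trace convergence")
    final = reconstruct_fes(hills, grid)
    basins, _ = find_basins_barriers(final, n_basins_max=n_basins_max)
    if len(basins) < 2:
        raise ValueError("fewer than two basins on the final surface")
    rows = []
    for t in checkpoints:
        n = int(np.searchsorted(hills.deposit_times, t, side="right"))
        if n == 0:
            continue
        fes_t = reconstruct_fes(hills, grid, n_hills=n)
        saddles = _watershed_saddles(
            fes_t.F, fes_t.periodic_flags, [b.grid_index for b in basins]
        )
        for (a, b), (f_saddle, _) in sorted(saddles.items()):
            rows.append(
                {
                    "time": t,
                    "from": basins[a].label,
                    "to": basins[b].label,
                    "delta_f": f_saddle - float(fes_t.F[basins[a].grid_index]),
                }
            )
    return pd.DataFrame(rows)
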