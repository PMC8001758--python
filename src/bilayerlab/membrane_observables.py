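"""Per-frame bilayer structure, probe tracking, torsions and residence times.

Observables follow the standard membrane-simulation definitions: the area
per lipid is the lateral box area divided by the lipid-plus-cholesterol
count of ONE leaflet; the thickness is the distance between the mean
phosphate z of the two leaflets; the probe position is tracked as its
centre-of-mass z relative to the bilayer midplane.  Statistical errors on
windowed means use block averaging (5 blocks by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trajectory_io import CVMeta, CVSeries, Trajectory, wrap_degrees

__all__ = [
    "BilayerSeries",
    "ResidenceReport",
    "area_per_lipid",
    "thickness",
    "bilayer_series",
    "probe_z_series",
    "dihedral",
    "classify_conformer",
    "classify_series",
    "residence_episodes",
    "block_stats",
    "FOLDED_WINDOW",
    "EXTENDED_WINDOW",
]

#: |psi| windows (degrees) assigning the two torsional conformers, taken as
#: mean +/- 2.5 sd of the observed conformer distributions (81 +/- 10 and
#: 170 +/- 23, the upper edge capped at 180).
FOLDED_WINDOW: tuple[float, float] = (56.0, 106.0)
EXTENDED_WINDOW: tuple[float, float] = (124.0, 180.0)


def block_stats(values: np.ndarray, n_blocks: int = 5) -> tuple[float, float]:
    """Mean and block-averaged standard error of a time series.

    The series is split into ``n_blocks`` contiguous blocks; the SE is the
    standard deviation of the block means over sqrt(n_blocks).  For fewer
    frames than blocks the plain SE of the mean is returned.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot compute statistics of an empty series")
    mean = float(v.mean())
    if v.size < n_blocks:
        se = float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else 0.0
        return mean, se
    blocks = np.array_split(v, n_blocks)
    bm = np.array([b.mean() for b in blocks])
    return mean, float(bm.std(ddof=1) / np.sqrt(n_blocks))


@dataclass
class BilayerSeries:
    """Per-frame area per lipid and thickness with windowed statistics."""

    times: np.ndarray
    area_per_lipid: np.ndarray   # nm^2
    thickness: np.ndarray        # nm
    area_mean: float
    area_se: float
    thickness_mean: float
    thickness_se: float


@dataclass
class ResidenceReport:
    """Continuous-residence episodes of a probe within a z slab."""

    episodes: list[tuple[float, float, float]]  # (start ps, end ps, duration ps)
    mean_lifetime: float                        # ps
    occupancy: float                            # fraction of total time in slab


def area_per_lipid(box_xy: tuple[float, float], n_lipids_leaflet: int, n_chol_leaflet: int = 0) -> float:
    """Area per lipid A = Lx*Ly / (Nl + Nchol) for ONE leaflet, nm^2.

    Cholesterol molecules count identically to lipids in the denominator.
    """
    denom = n_lipids_leaflet + n_chol_leaflet
    if denom < 1:
        raise ValueError("leaflet must contain at least one lipid or cholesterol")
    lx, ly = box_xy
    return lx * ly / denom


def thickness(frame_coords: np.ndarray, upper_idx: np.ndarray, lower_idx: np.ndarray) -> float:
    """Bilayer thickness |mean z(upper phosphates) - mean z(lower)|, nm."""
    upper_idx = np.asarray(upper_idx, dtype=int)
    lower_idx = np.asarray(lower_idx, dtype=int)
    if upper_idx.size == 0 or lower_idx.size == 0:
        raise ValueError("both phosphate groups must be non-empty")
    z = np.asarray(frame_coords)[:, 2]
    return float(abs(z[upper_idx].mean() - z[lower_idx].mean()))


def bilayer_series(
    traj: Trajectory,
    n_lipids_leaflet: int | None = None,
    n_chol_leaflet: int | None = None,
    upper: str = "P_upper",
    lower: str = "P_lower",
    n_blocks: int = 5,
) -> BilayerSeries:
    """Per-frame area per lipid and thickness for a whole trajectory.

    Leaflet composition defaults to the trajectory's own ``lipid``/``chol``
    groups (half of each, assuming symmetric leaflets).
    """
    up = traj.group(upper)
    lo = traj.group(lower)
    if n_lipids_leaflet is None:
        n_lipids_leaflet = len(traj.group("lipid")) // 2 if "lipid" in traj.groups else len(up)
    if n_chol_leaflet is None:
        n_chol_leaflet = len(traj.group("chol")) // 2 if "chol" in traj.groups else 0
    areas = np.array(
        [
            area_per_lipid((traj.box[f, 0], traj.box[f, 1]), n_lipids_leaflet, n_chol_leaflet)
            for f in range(traj.n_frames)
        ]
    )
    thick = np.array([thickness(traj.coords[f], up, lo) for f in range(traj.n_frames)])
    a_mean, a_se = block_stats(areas, n_blocks)
    t_mean, t_se = block_stats(thick, n_blocks)
    return BilayerSeries(
        times=traj.times.copy(),
        area_per_lipid=areas,
        thickness=thick,
        area_mean=a_mean,
        area_se=a_se,
        thickness_mean=t_mean,
        thickness_se=t_se,
    )


def probe_z_series(
    traj: Trajectory,
    probe: str = "probe",
    upper: str = "P_upper",
    lower: str = "P_lower",
    masses: np.ndarray | None = None,
) -> CVSeries:
    """Probe centre-of-mass z relative to the bilayer midplane, per frame.

    The midplane is the mean of the two leaflet mean-z values per frame, so
    the series is invariant under a rigid z translation of each frame.
    Unit masses are assumed unless ``masses`` (one per probe particle) is
    given.
    """
    p = traj.group(probe)
    up = traj.group(upper)
    lo = traj.group(lower)
    if p.size == 0 or up.size == 0 or lo.size == 0:
        raise ValueError("probe and both leaflet groups must be non-empty")
    if masses is None:
        w = np.full(p.size, 1.0)
    else:
        w = np.asarray(masses, dtype=float)
        if w.shape != (p.size,):
            raise ValueError("masses must provide one value per probe particle")
    w = w / w.sum()
    z = traj.coords[:, :, 2]
    probe_z = z[:, p] @ w
    midplane = 0.5 * (z[:, up].mean(axis=1) + z[:, lo].mean(axis=1))
    return CVSeries(
        times=traj.times.copy(),
        values=probe_z - midplane,
        cv_meta=[CVMeta(name="z", unit="nm")],
    )


def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle of four points, degrees on (-180, 180].

    Standard atan2 construction on the two plane normals; the sign follows
    the IUPAC convention (cis = 0, trans = 180).
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    eps = 1e-12
    if min(np.linalg.norm(b) for b in (b1, b2, b3)) < eps:
        raise ValueError("degenerate geometry: consecutive points coincide")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < eps or np.linalg.norm(n2) < eps:
        raise ValueError("degenerate geometry: three collinear points")
    x = float(n1 @ n2)
    y = float(np.cross(n1, n2) @ (b2 / np.linalg.norm(b2)))
    ang = np.degrees(np.arctan2(y, x))
    return wrap_degrees(ang)


def classify_conformer(psi: float) -> str:
    """Assign a torsion to the folded/extended conformer windows on |psi|.

    folded for |psi| in [56, 106], extended for |psi| in [124, 180],
    otherwise ``"unassigned"``.  Symmetric in the sign of psi.
    """
    a = abs(float(psi))
    if a > 180.0:
        raise ValueError("psi must lie in (-180, 180]")
    if FOLDED_WINDOW[0] <= a <= FOLDED_WINDOW[1]:
        return "folded"
    if EXTENDED_WINDOW[0] <= a <= EXTENDED_WINDOW[1]:
        return "extended"
    return "unassigned"


def classify_series(psi: np.ndarray) -> list[str]:
    """Vector version of :func:`classify_conformer`."""
    return [classify_conformer(p) for p in np.asarray(psi, dtype=float)]


def residence_episodes(
    z_series: CVSeries,
    slab: tuple[float, float],
    min_gap: float = 0.0,
    cv: str | int = 0,
) -> ResidenceReport:
    """Continuous-residence episodes of a probe within a z slab.

    A residence episode is a maximal run of frames with z in [z_lo, z_hi];
    two episodes separated by an excursion strictly shorter than ``min_gap``
    (ps) are merged, treating brief recrossings as part of one adsorption
    event.  Episode durations count one frame spacing per resident frame so
    that a fully-resident series has occupancy exactly 1.
    """
    z_lo, z_hi = slab
    if z_lo >= z_hi:
        raise ValueError("slab bounds must satisfy z_lo < z_hi")
    values = z_series.values[:, cv] if isinstance(cv, int) else z_series.column(cv)
    times = z_series.times
    if times.size == 0:
        raise ValueError("empty series")
    if times.size > 1:
        dt = float(np.mean(np.diff(times)))
    else:
        dt = 1.0
    inside = (values >= z_lo) & (values <= z_hi)

    # maximal runs of inside frames, as (first, last) frame indices
    runs: list[list[int]] = []
    for i, flag in enumerate(inside):
        if flag:
            if runs and runs[-1][1] == i - 1:
                runs[-1][1] = i
            else:
                runs.append([i, i])

    # merge runs separated by excursions shorter than min_gap
    merged: list[list[int]] = []
    for run in runs:
        if merged and (run[0] - merged[-1][1] - 1) * dt < min_gap:
            merged[-1][1] = run[1]
        else:
            merged.append(run)

    episodes = []
    total = 0.0
    for first, last in merged:
        duration = (last - first + 1) * dt
        episodes.append((float(times[first]), float(times[last]), float(duration)))
        total += duration
    span = times.size * dt
    mean_lifetime = total / len(episodes) if episodes else 0.0
    return ResidenceReport(
        episodes=episodes,
        mean_lifetime=float(mean_lifetime),
        occupancy=float(min(total / span, 1.0)),
    )
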