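"""Trajectory, CV-series and hill-log containers plus their text-file dialects.

Formats
-------
Multi-frame XYZ
    Per frame: a particle-count line, a comment line carrying time and box in
    the micro-format ``t=<val> ps box=<Lx> <Ly> <Lz>`` (nm), then one
    ``<label> <x> <y> <z>`` line per particle (nm).  XYZ has no standard for
    time or box, so the comment micro-format is defined here.

GRO (GROMACS coordinate format)
    Fixed-column records, nm; multi-frame files are concatenated blocks, each
    ending in a box line.  Only orthorhombic boxes (three box numbers) are
    accepted.  Positions carry three decimals, so GRO roundtrips are exact to
    0.001 nm only.

COLVAR / HILLS
    Whitespace-separated columns under a ``#! FIELDS time ...`` header, the
    dialect written by the PLUMED plugin.  Optional ``#! SET period_<cv> <p>``
    and ``#! SET unit_<cv> <u>`` lines declare periodicity and units of a CV
    column.  HILLS columns are ``time <center per CV> <sigma per CV> height
    biasf``.

All readers convert on ingest and all writers on output so that in-memory
objects are always in nm / ps / kJ/mol / degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FormatError",
    "Trajectory",
    "CVMeta",
    "CVSeries",
    "HillLog",
    "read_xyz",
    "write_xyz",
    "read_gro",
    "write_gro",
    "read_colvar",
    "write_colvar",
    "read_hills",
    "write_hills",
    "wrap_degrees",
]


class FormatError(ValueError):
    """Raised when a trajectory/CV/hill file violates its declared format."""


def wrap_degrees(angle):
    """Wrap angles in degrees onto the interval (-180, 180]."""
    a = np.mod(np.asarray(angle, dtype=float), 360.0)
    a = np.where(a > 180.0, a - 360.0, a)
    if np.ndim(angle) == 0:
        return float(a)
    return a


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class Trajectory:
    """In-memory multi-frame trajectory with orthorhombic periodic boxes.

    Attributes
    ----------
    times : (n_frames,) float array, ps; strictly increasing.
    coords : (n_frames, n_particles, 3) float array, nm.
    box : (n_frames, 3) float array of edge lengths (Lx, Ly, Lz), nm.
    labels : per-particle species/site tags.
    groups : named particle index sets, e.g. ``"P_upper"``, ``"probe"``.
    """

    times: np.ndarray
    coords: np.ndarray
    box: np.ndarray
    labels: list[str]
    groups: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        self.labels = list(self.labels)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError(
                f"coords must have shape (n_frames, n_particles, 3), got {self.coords.shape}"
            )
        n_frames, n_particles, _ = self.coords.shape
        if self.times.shape != (n_frames,):
            raise ValueError("times length must equal the number of frames")
        if n_frames > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.box.shape != (n_frames, 3):
            raise ValueError("box must have shape (n_frames, 3)")
        if not np.all(self.box > 0):
            raise ValueError("all box edges must be positive")
        if len(self.labels) != n_particles:
            raise ValueError("labels length must equal the particle count")
        for name, idx in self.groups.items():
            idx = np.asarray(idx, dtype=int)
            self.groups[name] = idx
            if idx.size and (idx.min() < 0 or idx.max() >= n_particles):
                raise ValueError(f"group {name!r} has out-of-range particle indices")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_particles(self) -> int:
        return self.coords.shape[1]

    def group(self, name: str) -> np.ndarray:
        try:
            return self.groups[name]
        except KeyError:
            raise KeyError(
                f"group {name!r} not defined; available: {sorted(self.groups)}"
            ) from None


@dataclass(frozen=True)
class CVMeta:
    """Metadata for one collective-variable column."""

    name: str
    unit: str = "nm"          # "nm" or "degrees"
    periodic: bool = False
    period: float = 0.0       # only meaningful when periodic

    def __post_init__(self) -> None:
        if self.periodic and self.period <= 0:
            raise ValueError(f"periodic CV {self.name!r} needs a positive period")


@dataclass
class CVSeries:
    """Time series of one or more collective variables.

    ``values`` has one column per CV.  Periodic CVs are stored wrapped into
    one period: degrees on (-180, 180] for the conventional 360-degree case.
    """

    times: np.ndarray
    values: np.ndarray
    cv_meta: list[CVMeta]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        if self.times.shape[0] != self.values.shape[0]:
            raise ValueError("times and values must have the same length")
        if len(self.cv_meta) != self.values.shape[1]:
            raise ValueError("one CVMeta per value column required")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        for j, meta in enumerate(self.cv_meta):
            if meta.periodic:
                half = meta.period / 2.0
                col = self.values[:, j]
                if col.size and (col.min() <= -half - 1e-9 or col.max() > half + 1e-9):
                    raise ValueError(
                        f"periodic CV {meta.name!r} has values outside (-{half}, {half}]"
                    )

    @property
    def n_cv(self) -> int:
        return self.values.shape[1]

    @property
    def names(self) -> list[str]:
        return [m.name for m in self.cv_meta]

    def column(self, name: str) -> np.ndarray:
        try:
            j = self.names.index(name)
        except ValueError:
            raise KeyError(f"no CV named {name!r}; have {self.names}") from None
        return self.values[:, j]


@dataclass
class HillLog:
    """Gaussian hills deposited by a well-tempered metadynamics run.

    Heights are the already-tempered deposit heights in kJ/mol; the bias
    factor gamma is a single dimensionless constant for the whole run.
    """

    deposit_times: np.ndarray
    centers: np.ndarray
    widths: np.ndarray
    heights: np.ndarray
    bias_factor: float
    cv_meta: list[CVMeta] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.deposit_times = np.asarray(self.deposit_times, dtype=float)
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        self.widths = np.atleast_2d(np.asarray(self.widths, dtype=float))
        self.heights = np.asarray(self.heights, dtype=float)
        n = self.deposit_times.shape[0]
        if self.centers.shape[0] != n or self.widths.shape[0] != n or self.heights.shape[0] != n:
            raise ValueError("deposit_times, centers, widths and heights must align")
        if self.centers.shape != self.widths.shape:
            raise ValueError("centers and widths must have the same shape")
        if n and not np.all(np.diff(self.deposit_times) >= 0):
            raise ValueError("deposit_times must be non-decreasing")
        if n and not np.all(self.widths > 0):
            raise ValueError("all hill widths must be positive")
        if n and not np.all(self.heights > 0):
            raise ValueError("all hill heights must be positive")
        if self.bias_factor <= 1:
            raise ValueError("bias_factor must exceed 1")
        if not self.cv_meta:
            self.cv_meta = [CVMeta(name=f"cv{j+1}") for j in range(self.centers.shape[1])]
        if len(self.cv_meta) != self.centers.shape[1]:
            raise ValueError("one CVMeta per CV column required")

    @property
    def n_hills(self) -> int:
        return self.deposit_times.shape[0]

    @property
    def n_cv(self) -> int:
        return self.centers.shape[1]


# ---------------------------------------------------------------------------
# XYZ
# ---------------------------------------------------------------------------

_XYZ_FLOAT = "%.6f"


def _parse_xyz_comment(line: str, lineno: int) -> tuple[float, np.ndarray]:
    # micro-format: "t=<val> ps box=<Lx> <Ly> <Lz>"
    try:
        tpart, bpart = line.split("box=")
        tval = float(tpart.split("t=")[1].split()[0])
        box = np.array([float(x) for x in bpart.split()[:3]])
    except (IndexError, ValueError):
        raise FormatError(
            f"line {lineno}: comment line must read 't=<val> ps box=<Lx> <Ly> <Lz>', got {line!r}"
        ) from None
    if box.shape != (3,):
        raise FormatError(f"line {lineno}: box needs three edge lengths")
    return tval, box


def read_xyz(path) -> Trajectory:
    """Read a multi-frame XYZ file (nm, ps) into a :class:`Trajectory`."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    times, boxes, frames = [], [], []
    labels: list[str] | None = None
    i = 0
    frame_no = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        frame_no += 1
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise FormatError(f"line {i+1}: expected particle count, got {lines[i]!r}") from None
        if i + 1 >= len(lines):
            raise FormatError(f"frame {frame_no}: truncated before comment line")
        t, box = _parse_xyz_comment(lines[i + 1], i + 2)
        coords = np.empty((n, 3))
        frame_labels = []
        for k in range(n):
            lineno = i + 2 + k
            if lineno >= len(lines):
                raise FormatError(f"frame {frame_no}: truncated after {k} of {n} particles")
            parts = lines[lineno].split()
            if len(parts) != 4:
                raise FormatError(
                    f"line {lineno+1}: expected '<label> <x> <y> <z>', got {lines[lineno]!r}"
                )
            frame_labels.append(parts[0])
            try:
                coords[k] = [float(v) for v in parts[1:]]
            except ValueError:
                raise FormatError(f"line {lineno+1}: unparsable coordinate in {lines[lineno]!r}") from None
        if labels is None:
            labels = frame_labels
        elif len(frame_labels) != len(labels):
            raise FormatError(
                f"frame {frame_no}: particle count {len(frame_labels)} differs from frame 1 ({len(labels)})"
            )
        times.append(t)
        boxes.append(box)
        frames.append(coords)
        i += 2 + n
    if not frames:
        raise FormatError("file contains no frames")
    return Trajectory(
        times=np.array(times), coords=np.stack(frames), box=np.stack(boxes), labels=labels
    )


def write_xyz(traj: Trajectory, path) -> None:
    """Write a :class:`Trajectory` as multi-frame XYZ (nm, ps)."""
    if traj.n_frames == 0:
        raise ValueError("cannot write a trajectory with zero frames")
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{traj.n_particles}\n")
            bx, by, bz = traj.box[f]
            fh.write(
                f"t={_XYZ_FLOAT % traj.times[f]} ps box="
                f"{_XYZ_FLOAT % bx} {_XYZ_FLOAT % by} {_XYZ_FLOAT % bz}\n"
            )
            for lab, (x, y, z) in zip(traj.labels, traj.coords[f]):
                fh.write(f"{lab} {_XYZ_FLOAT % x} {_XYZ_FLOAT % y} {_XYZ_FLOAT % z}\n")


# ---------------------------------------------------------------------------
# GRO
# ---------------------------------------------------------------------------


def read_gro(path) -> Trajectory:
    """Read a single- or multi-frame GRO file (fixed columns, nm)."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    times, boxes, frames = [], [], []
    labels: list[str] | None = None
    i = 0
    frame_no = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        frame_no += 1
        title = lines[i]
        if i + 1 >= len(lines):
            raise FormatError(f"frame {frame_no}: truncated before atom-count line")
        try:
            n = int(lines[i + 1].strip())
        except ValueError:
            raise FormatError(
                f"line {i+2}: expected atom count, got {lines[i+1]!r}"
            ) from None
        if i + 2 + n >= len(lines):
            raise FormatError(f"frame {frame_no}: missing box line (file truncated)")
        t = float(frame_no - 1)
        if "t=" in title:
            try:
                t = float(title.split("t=")[1].split()[0])
            except (IndexError, ValueError):
                raise FormatError(f"line {i+1}: unparsable time in title {title!r}") from None
        coords = np.empty((n, 3))
        frame_labels = []
        for k in range(n):
            line = lines[i + 2 + k]
            if len(line) < 44:
                raise FormatError(
                    f"line {i+3+k}: GRO atom record shorter than fixed-column width"
                )
            atom_name = line[10:15].strip()
            try:
                coords[k] = [float(line[20:28]), float(line[28:36]), float(line[36:44])]
            except ValueError:
                raise FormatError(
                    f"line {i+3+k}: fixed-column misalignment in {line!r}"
                ) from None
            frame_labels.append(atom_name)
        box_parts = lines[i + 2 + n].split()
        if len(box_parts) < 3:
            raise FormatError(f"line {i+3+n}: box line needs three edge lengths")
        if len(box_parts) > 3 and any(float(v) != 0.0 for v in box_parts[3:]):
            raise FormatError("triclinic boxes are not supported (off-diagonal box elements)")
        try:
            box = np.array([float(v) for v in box_parts[:3]])
        except ValueError:
            raise FormatError(f"line {i+3+n}: unparsable box line {lines[i+2+n]!r}") from None
        if labels is None:
            labels = frame_labels
        elif len(frame_labels) != len(labels):
            raise FormatError(
                f"frame {frame_no}: atom count {len(frame_labels)} differs from frame 1"
            )
        times.append(t)
        boxes.append(box)
        frames.append(coords)
        i += 3 + n
    if not frames:
        raise FormatError("file contains no frames")
    return Trajectory(
        times=np.array(times), coords=np.stack(frames), box=np.stack(boxes), labels=labels
    )


def write_gro(traj: Trajectory, path) -> None:
    """Write a :class:`Trajectory` as (multi-frame) GRO.

    Every particle is emitted as its own residue named after its label
    (truncated to five characters, per the fixed-column format).  Positions
    are printed with three decimals, the format's native precision.
    """
    if traj.n_frames == 0:
        raise ValueError("cannot write a trajectory with zero frames")
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"bilayerlab frame t={traj.times[f]:.6f}\n")
            fh.write(f"{traj.n_particles:5d}\n")
            for k, (lab, (x, y, z)) in enumerate(zip(traj.labels, traj.coords[f])):
                resid = (k % 99999) + 1
                name = lab[:5]
                fh.write(f"{resid:5d}{name:<5s}{name:>5s}{(k % 99999) + 1:5d}{x:8.3f}{y:8.3f}{z:8.3f}\n")
            bx, by, bz = traj.box[f]
            fh.write(f"{bx:10.5f}{by:10.5f}{bz:10.5f}\n")


# ---------------------------------------------------------------------------
# COLVAR / HILLS
# ---------------------------------------------------------------------------


def _read_fields_table(path) -> tuple[list[str], dict[str, str], np.ndarray]:
    with open(path) as fh:
        lines = fh.read().splitlines()
    fields: list[str] | None = None
    sets: dict[str, str] = {}
    rows = []
    for lineno, line in enumerate(lines, start=1):
        s = line.strip()
        if not s:
            continue
        if s.startswith("#!"):
            parts = s.split()
            if len(parts) >= 2 and parts[1] == "FIELDS":
                fields = parts[2:]
            elif len(parts) >= 4 and parts[1] == "SET":
                sets[parts[2]] = parts[3]
            continue
        if fields is None:
            raise FormatError(f"line {lineno}: data before '#! FIELDS' header")
        vals = s.split()
        if len(vals) != len(fields):
            raise FormatError(
                f"line {lineno}: row has {len(vals)} columns but header declares {len(fields)}"
            )
        try:
            rows.append([float(v) for v in vals])
        except ValueError:
            raise FormatError(f"line {lineno}: unparsable number in {s!r}") from None
    if fields is None:
        raise FormatError("missing '#! FIELDS' header")
    data = np.array(rows, dtype=float) if rows else np.empty((0, len(fields)))
    return fields, sets, data


def _meta_from_sets(names: list[str], sets: dict[str, str]) -> list[CVMeta]:
    meta = []
    for name in names:
        period = float(sets.get(f"period_{name}", 0.0))
        unit = sets.get(f"unit_{name}", "degrees" if period else "nm")
        meta.append(CVMeta(name=name, unit=unit, periodic=period > 0, period=period))
    return meta


def read_colvar(path) -> CVSeries:
    """Read a PLUMED-dialect COLVAR file into a :class:`CVSeries`."""
    fields, sets, data = _read_fields_table(path)
    if not fields or fields[0] != "time":
        raise FormatError("first FIELDS column must be 'time'")
    names = fields[1:]
    if not names:
        raise FormatError("COLVAR file declares no CV columns")
    return CVSeries(times=data[:, 0], values=data[:, 1:], cv_meta=_meta_from_sets(names, sets))


def write_colvar(series: CVSeries, path) -> None:
    """Write a :class:`CVSeries` as a PLUMED-dialect COLVAR file."""
    with open(path, "w") as fh:
        fh.write("#! FIELDS time " + " ".join(series.names) + "\n")
        for m in series.cv_meta:
            fh.write(f"#! SET unit_{m.name} {m.unit}\n")
            if m.periodic:
                fh.write(f"#! SET period_{m.name} {m.period:g}\n")
        for t, row in zip(series.times, series.values):
            fh.write(" ".join(_XYZ_FLOAT % v for v in (t, *row)) + "\n")


def read_hills(path) -> HillLog:
    """Read a PLUMED-dialect HILLS file into a :class:`HillLog`."""
    fields, sets, data = _read_fields_table(path)
    if not fields or fields[0] != "time" or fields[-2:] != ["height", "biasf"]:
        raise FormatError("HILLS header must be 'time <centers> <sigmas> height biasf'")
    cv_cols = fields[1:-2]
    if len(cv_cols) % 2 != 0:
        raise FormatError("HILLS header must pair each CV with a sigma_<cv> column")
    n_cv = len(cv_cols) // 2
    names = cv_cols[:n_cv]
    for j, name in enumerate(names):
        if cv_cols[n_cv + j] != f"sigma_{name}":
            raise FormatError(f"expected column 'sigma_{name}', got {cv_cols[n_cv + j]!r}")
    if data.shape[0] == 0:
        raise FormatError("HILLS file contains no hills")
    times = data[:, 0]
    if not np.all(np.diff(times) >= 0):
        raise FormatError("hill deposit times must be non-decreasing")
    biasf = data[:, -1]
    if not np.allclose(biasf, biasf[0]):
        raise FormatError("bias factor must be constant across all hills")
    return HillLog(
        deposit_times=times,
        centers=data[:, 1 : 1 + n_cv],
        widths=data[:, 1 + n_cv : 1 + 2 * n_cv],
        heights=data[:, -2],
        bias_factor=float(biasf[0]),
        cv_meta=_meta_from_sets(names, sets),
    )


def write_hills(log: HillLog, path) -> None:
    """Write a :class:`HillLog` as a PLUMED-dialect HILLS file."""
    names = [m.name for m in log.cv_meta]
    with open(path, "w") as fh:
        fh.write(
            "#! FIELDS time "
            + " ".join(names)
            + " "
            + " ".join(f"sigma_{n}" for n in names)
            + " height biasf\n"
        )
        for m in log.cv_meta:
            fh.write(f"#! SET unit_{m.name} {m.unit}\n")
            if m.periodic:
                fh.write(f"#! SET period_{m.name} {m.period:g}\n")
        for k in range(log.n_hills):
            row = (
                log.deposit_times[k],
                *log.centers[k],
                *log.widths[k],
                log.heights[k],
                log.bias_factor,
            )
            fh.write(" ".join(_XYZ_FLOAT % v for v in row) + "\n")
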