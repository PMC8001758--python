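"""Mean-square displacement and Einstein-relation diffusion coefficients.

MSD uses all available time origins per lag; the diffusion coefficient
follows from the Einstein relation D = slope / (2 d) of the long-time MSD,
with d the dimensionality of the motion (d = 2 for lateral, in-plane
diffusion).  Standard errors come from refitting on 5 contiguous time
blocks.  Coordinates must be unwrapped (no periodic jumps); an ``unwrap``
helper removes jumps by minimum-image step correction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .constants import NM2_PER_PS_TO_CM2_PER_S
from .trajectory_io import Trajectory

__all__ = ["MSDResult", "msd", "fit_diffusion", "unwrap"]

_DIM_INDEX = {"x": 0, "y": 1, "z": 2}


@dataclass
class MSDResult:
    """MSD curve and (optionally) its Einstein-relation diffusion fit."""

    lags: np.ndarray          # ps
    msd: np.ndarray           # nm^2
    n_origins: np.ndarray     # origins averaged per lag
    dims: tuple[str, ...]     # subset of ("x", "y", "z") used
    # fit results, populated by fit_diffusion
    d: int | None = None                      # dimensionality used in the fit
    fit_window: tuple[float, float] | None = None  # (lag_lo, lag_hi) ps
    D: float | None = None                    # cm^2/s
    D_se: float | None = None                 # cm^2/s
    slope: float | None = None                # nm^2/ps
    intercept: float | None = None            # nm^2
    r_squared: float | None = None
    reliable: bool = True


class _RawBlock:
    """Pre-selected positions of one contiguous trajectory block."""

    def __init__(self, times, pos, box):
        self.times = times
        self.pos = pos
        self.box = box


def _select_positions(source, group, dims) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    """(times, positions (n_frames, n_particles, n_dims), box or None)."""
    cols = tuple(dims)
    for c in cols:
        if c not in _DIM_INDEX:
            raise ValueError(f"unknown dimension {c!r}; use a subset of x, y, z")
    j = [_DIM_INDEX[c] for c in cols]
    if isinstance(source, _RawBlock):
        return source.times, source.pos, source.box
    if isinstance(source, Trajectory):
        idx = source.group(group) if group is not None else np.arange(source.n_particles)
        if idx.size == 0:
            raise ValueError("selected group is empty")
        return source.times, source.coords[:, idx][:, :, j], source.box[:, j]
    # CVSeries-like: treat each column as one coordinate of a single particle
    return source.times, source.values[:, None, :], None


def msd(source, group: str | None = None, dims=("x", "y")) -> MSDResult:
    """Multiple-time-origin mean-square displacement.

    MSD(tau) = < |r(t+tau) - r(t)|^2 > over all valid origins t and over the
    particles of ``group``, restricted to the chosen dimensions.  Requires
    uniform time spacing and unwrapped coordinates: any single-frame step
    larger than half the box in a used dimension raises, advising
    :func:`unwrap`.
    """
    times, pos, box = _select_positions(source, group, dims)
    n_frames = pos.shape[0]
    if n_frames < 2:
        raise ValueError("need at least two frames for an MSD")
    dt_steps = np.diff(times)
    dt = dt_steps[0]
    if not np.allclose(dt_steps, dt, rtol=1e-6, atol=1e-9):
        raise ValueError("MSD requires uniformly spaced frames")
    if box is not None:
        steps = np.abs(np.diff(pos, axis=0))
        half = box[:-1, None, :] / 2.0
        if np.any(steps > half):
            raise ValueError(
                "wrapped-coordinate jump detected (step larger than half the box); "
                "unwrap the trajectory first (see bilayerlab.dynamics.unwrap)"
            )
    n_lags = n_frames
    n_origins = n_frames - np.arange(n_lags)
    out = np.zeros(n_lags)
    for p in range(pos.shape[1]):
        out += _msd_fft_single(pos[:, p, :])
    out /= pos.shape[1]
    out[0] = 0.0                      # identically zero; remove FFT roundoff
    np.clip(out, 0.0, None, out=out)
    return MSDResult(
        lags=np.arange(n_lags) * dt,
        msd=out,
        n_origins=n_origins,
        dims=tuple(dims),
    )


def _msd_fft_single(x: np.ndarray) -> np.ndarray:
    """All-origin MSD of one particle via FFT autocorrelation, O(n log n).

    Identical (to floating-point roundoff) to the double loop
    ``mean_t |x(t+tau) - x(t)|^2``: expanding the square gives a running sum
    of squared norms plus an autocorrelation term computed by FFT.
    """
    n = x.shape[0]
    sq = (x**2).sum(axis=1)
    # autocorrelation sum_t x_t . x_{t+tau} per dimension, zero-padded FFT
    nfft = 1 << (2 * n - 1).bit_length()
    acf = np.zeros(n)
    for jdim in range(x.shape[1]):
        f = np.fft.rfft(x[:, jdim], nfft)
        acf += np.fft.irfft(f * f.conjugate(), nfft)[:n]
    prefix = np.cumsum(sq)
    total = prefix[-1]
    tau = np.arange(n)
    # sum over valid origins of (|x_t|^2 + |x_{t+tau}|^2)
    head = prefix[n - 1 - tau]
    tail = total - np.concatenate(([0.0], prefix[:-1]))[tau]
    return (head + tail - 2.0 * acf) / (n - tau)


def fit_diffusion(
    result_or_source,
    d: int = 2,
    window: tuple[float, float] = (0.10, 0.50),
    group: str | None = None,
    dims=("x", "y"),
    n_blocks: int = 5,
) -> MSDResult:
    """Einstein-relation diffusion coefficient from the MSD slope.

    A least-squares line is fitted to MSD vs lag over ``window`` (fractions
    of the maximum lag; default 10-50%, skipping the noisy short-lag and
    origin-starved long-lag regimes), and D = slope / (2 d), converted to
    cm^2/s.  The standard error is the spread (std) of D refitted on
    ``n_blocks`` contiguous trajectory blocks: because the fit window scales
    with the series length, the estimator's sampling variance does not
    shrink with trajectory length, so the block spread itself — not the
    spread over sqrt(n_blocks) — is the honest error of the full-series
    fit.  A negative slope flags the result unreliable instead of raising.
    """
    if isinstance(result_or_source, MSDResult):
        res = result_or_source
        source = None
    else:
        source = result_or_source
        res = msd(source, group=group, dims=dims)
    if d not in (1, 2, 3):
        raise ValueError("dimensionality d must be 1, 2 or 3")
    lo_f, hi_f = window
    if not (0 <= lo_f < hi_f <= 1):
        raise ValueError("window must be an increasing pair of fractions in [0, 1]")
    max_lag = res.lags[-1]
    sel = (res.lags >= lo_f * max_lag) & (res.lags <= hi_f * max_lag)
    if sel.sum() < 5:
        raise ValueError("fit window contains fewer than 5 lag points")
    x = res.lags[sel]
    y = res.msd[sel]
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_res = float(((y - yhat) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    d_est = slope / (2.0 * d) * NM2_PER_PS_TO_CM2_PER_S

    d_se = None
    if source is not None:
        block_ds = _block_diffusion(source, d, window, group, res.dims, n_blocks)
        if len(block_ds) >= 2:
            d_se = float(np.std(block_ds, ddof=1))
    return replace(
        res,
        d=d,
        fit_window=(float(x[0]), float(x[-1])),
        D=float(d_est),
        D_se=d_se,
        slope=float(slope),
        intercept=float(intercept),
        r_squared=float(r2),
        reliable=bool(slope > 0),
    )


def _block_diffusion(source, d, window, group, dims, n_blocks) -> list[float]:
    times, pos, box = _select_positions(source, group, dims)
    n = pos.shape[0]
    if n < n_blocks * 12:
        return []
    bounds = np.linspace(0, n, n_blocks + 1, dtype=int)
    out = []
    for b in range(n_blocks):
        sl = slice(bounds[b], bounds[b + 1])
        sub = _RawBlock(times[sl], pos[sl], None if box is None else box[sl])
        try:
            res = msd(sub, group=None, dims=dims)
            fit = fit_diffusion(res, d=d, window=window)
        except ValueError:
            continue
        out.append(fit.D)
    return out


def unwrap(traj: Trajectory, group: str | None = None) -> Trajectory:
    """Remove periodic jumps by minimum-image correction of successive steps.

    Returns a new trajectory whose coordinates evolve continuously; box and
    metadata are preserved.  With ``group`` only those particles are
    unwrapped (others are copied as-is).
    """
    coords = traj.coords.copy()
    idx = traj.group(group) if group is not None else np.arange(traj.n_particles)
    for f in range(1, traj.n_frames):
        box = traj.box[f]
        step = coords[f, idx] - coords[f - 1, idx]
        step -= box * np.round(step / box)
        coords[f, idx] = coords[f - 1, idx] + step
    return Trajectory(
        times=traj.times.copy(),
        coords=coords,
        box=traj.box.copy(),
        labels=list(traj.labels),
        groups={k: v.copy() for k, v in traj.groups.items()},
    )
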