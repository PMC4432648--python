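"""Rejection-sampling kinetic Monte Carlo simulator on rings and tori.

Algorithm (per attempt): pick one lattice site uniformly at random, pick one
of the seven elementary processes with probability proportional to its rate
constant, and apply it only if the local configuration permits it (e.g. a
melanophore can only be killed by a xanthophore if a randomly chosen first
neighbor actually holds one).  Whatever the outcome, the clock advances by
1/N0 where N0 is the number of nodes, so one time unit equals one sweep.

Neighbor-mediated processes draw ONE uniformly random neighbor from the
relevant neighborhood; this realises the neighborhood-average rate
convention assumed by the mean-field reduction in :mod:`digrow.meanfield`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numba import njit

from .model import (
    M,
    S,
    X,
    LatticeState,
    ModelParams,
    ProcessKind,
    axes_offsets,
    ring_offsets,
)

__all__ = [
    "SimConfig",
    "Trajectory",
    "process_probabilities",
    "attempt",
    "run",
    "with_irido_band",
]


@dataclass(frozen=True)
class SimConfig:
    """Run configuration for the stochastic simulator."""

    n_attempts: int
    seed: int
    shape: tuple[int, ...] = (100, 100)   # (width, height) or (N,)
    snapshot_every: int = 0               # 0: only the final snapshot
    initial: LatticeState | None = None   # None: uniform S
    neighborhood: str = "ring"            # long-range: "ring" or "axes"
    burn_in: int = 0                      # attempts excluded from time averages

    def __post_init__(self) -> None:
        if self.n_attempts < 1:
            raise ValueError("n_attempts must be >= 1")
        if not 0 <= self.burn_in < self.n_attempts:
            raise ValueError("burn_in must lie in [0, n_attempts)")
        if self.neighborhood not in ("ring", "axes"):
            raise ValueError("neighborhood must be 'ring' or 'axes'")


@dataclass
class Trajectory:
    """Recorded output of a KMC run."""

    snapshots: list[tuple[float, LatticeState]]
    params: ModelParams
    config: SimConfig
    rng_provenance: str
    #: time-averaged per-site X / M occupancy over the post-burn-in window
    site_x_mean: np.ndarray | None = None
    site_m_mean: np.ndarray | None = None
    #: global coverage means over equal post-burn-in batches (for MC errors)
    batch_x: np.ndarray | None = None
    batch_m: np.ndarray | None = None

    @property
    def final(self) -> LatticeState:
        return self.snapshots[-1][1]


def process_probabilities(params: ModelParams) -> np.ndarray:
    """Selection probabilities P_k = c_k / sum(c_j), ordered by ProcessKind."""
    rates = params.rates
    total = rates.sum()
    if total <= 0:
        raise ValueError("at least one rate constant must be positive")
    return rates / total


def _long_range_offset_arrays(params: ModelParams, ndim: int, neighborhood: str):
    if ndim == 1:
        dc = np.array([-params.h, params.h], dtype=np.int64)
        dr = np.zeros(2, dtype=np.int64)
        return dr, dc
    offs = ring_offsets(params.h) if neighborhood == "ring" else axes_offsets(params.h)
    # offsets are (dx, dy) = (dcol, drow)
    return offs[:, 1].astype(np.int64), offs[:, 0].astype(np.int64)


def _short_range_offset_arrays(ndim: int):
    if ndim == 1:
        return np.zeros(2, dtype=np.int64), np.array([-1, 1], dtype=np.int64)
    return (
        np.array([0, 0, -1, 1], dtype=np.int64),
        np.array([-1, 1, 0, 0], dtype=np.int64),
    )


# ---------------------------------------------------------------------------
# pure-Python reference attempt (single step; mirrors the compiled kernel)
# ---------------------------------------------------------------------------

def attempt(
    state: LatticeState,
    params: ModelParams,
    prob_table: np.ndarray,
    rng: np.random.Generator,
    neighborhood: str = "ring",
) -> LatticeState:
    """Perform one KMC attempt in place; the clock always advances by 1/N0.

    Three uniform variates are consumed per attempt in fixed order: site,
    process, neighbor (the last is drawn even when unused, to pin down the
    reproducibility contract).
    """
    occ = state.occupancy
    grid = occ if occ.ndim == 2 else occ[None, :]
    mask = state.irido_mask if occ.ndim == 2 else state.irido_mask[None, :]
    n_rows, n_cols = grid.shape
    n = grid.size
    cum = np.cumsum(prob_table)

    site = int(rng.random() * n)
    row, col = site // n_cols, site % n_cols
    p = int(np.searchsorted(cum, rng.random(), side="right"))
    p = min(p, 6)
    r_nb = rng.random()

    sr_dr, sr_dc = _short_range_offset_arrays(occ.ndim)
    lr_dr, lr_dc = _long_range_offset_arrays(params, occ.ndim, neighborhood)

    cur = grid[row, col]
    if p == ProcessKind.X_BIRTH and cur == S:
        grid[row, col] = X
    elif p == ProcessKind.M_BIRTH and cur == S and not mask[row, col]:
        grid[row, col] = M
    elif p == ProcessKind.X_DEATH and cur == X:
        grid[row, col] = S
    elif p == ProcessKind.M_DEATH and cur == M:
        grid[row, col] = S
    elif p == ProcessKind.X_KILLED_BY_M and cur == X:
        j = int(r_nb * len(sr_dr))
        if grid[(row + sr_dr[j]) % n_rows, (col + sr_dc[j]) % n_cols] == M:
            grid[row, col] = S
    elif p == ProcessKind.M_KILLED_BY_X and cur == M:
        j = int(r_nb * len(sr_dr))
        if grid[(row + sr_dr[j]) % n_rows, (col + sr_dc[j]) % n_cols] == X:
            grid[row, col] = S
    elif p == ProcessKind.M_BIRTH_LONGRANGE and cur == S and not mask[row, col]:
        j = int(r_nb * len(lr_dr))
        if grid[(row + lr_dr[j]) % n_rows, (col + lr_dc[j]) % n_cols] == X:
            grid[row, col] = M

    state.time += 1.0 / n
    return state


# ---------------------------------------------------------------------------
# compiled bulk kernel
# ---------------------------------------------------------------------------

@njit(cache=True)
def _kmc_kernel(
    grid,
    mask,
    cum,
    sr_dr,
    sr_dc,
    lr_dr,
    lr_dc,
    n_attempts,
    seed,
    snap_every,
    snaps,
    burn_in,
    site_x_sum,
    site_m_sum,
    batch_x,
    batch_m,
):  # pragma: no cover - exercised via run()
    np.random.seed(seed)
    n_rows, n_cols = grid.shape
    n = n_rows * n_cols
    n_sr = sr_dr.shape[0]
    n_lr = lr_dr.shape[0]
    n_batches = batch_x.shape[0]
    measure = n_attempts - burn_in

    last_t = np.full((n_rows, n_cols), burn_in, dtype=np.int64)

    n_x = 0
    n_m = 0
    for r in range(n_rows):
        for c in range(n_cols):
            if grid[r, c] == 1:
                n_x += 1
            elif grid[r, c] == 2:
                n_m += 1

    for t in range(1, n_attempts + 1):
        r1 = np.random.random()
        site = int(r1 * n)
        row = site // n_cols
        col = site % n_cols
        r2 = np.random.random()
        p = 0
        while p < 6 and r2 > cum[p]:
            p += 1
        r3 = np.random.random()

        cur = grid[row, col]
        new = cur
        if p == 0:
            if cur == 0:
                new = 1
        elif p == 1:
            if cur == 0 and not mask[row, col]:
                new = 2
        elif p == 2:
            if cur == 1:
                new = 0
        elif p == 3:
            if cur == 2:
                new = 0
        elif p == 4:
            if cur == 1:
                j = int(r3 * n_sr)
                nr = (row + sr_dr[j]) % n_rows
                nc = (col + sr_dc[j]) % n_cols
                if grid[nr, nc] == 2:
                    new = 0
        elif p == 5:
            if cur == 2:
                j = int(r3 * n_sr)
                nr = (row + sr_dr[j]) % n_rows
                nc = (col + sr_dc[j]) % n_cols
                if grid[nr, nc] == 1:
                    new = 0
        else:
            if cur == 0 and not mask[row, col]:
                j = int(r3 * n_lr)
                nr = (row + lr_dr[j]) % n_rows
                nc = (col + lr_dc[j]) % n_cols
                if grid[nr, nc] == 1:
                    new = 2

        if new != cur:
            if t > burn_in:
                dt = t - last_t[row, col]
                if cur == 1:
                    site_x_sum[row, col] += dt
                elif cur == 2:
                    site_m_sum[row, col] += dt
                last_t[row, col] = t
            grid[row, col] = new
            if cur == 1:
                n_x -= 1
            elif cur == 2:
                n_m -= 1
            if new == 1:
                n_x += 1
            elif new == 2:
                n_m += 1

        if t > burn_in and n_batches > 0:
            b = (t - burn_in - 1) * n_batches // measure
            batch_x[b] += n_x
            batch_m[b] += n_m

        if snap_every > 0 and t % snap_every == 0:
            idx = t // snap_every - 1
            if idx < snaps.shape[0]:
                snaps[idx] = grid

    # flush per-site occupancy time integrals
    for r in range(n_rows):
        for c in range(n_cols):
            dt = n_attempts + 1 - last_t[r, c]
            if grid[r, c] == 1:
                site_x_sum[r, c] += dt
            elif grid[r, c] == 2:
                site_m_sum[r, c] += dt


def run(params: ModelParams, config: SimConfig) -> Trajectory:
    """Execute a full KMC run; fully reproducible given ``config.seed``."""
    if config.initial is not None:
        state = config.initial.copy()
    else:
        state = LatticeState.all_s(
            config.shape if len(config.shape) > 1 else config.shape[0]
        )
    occ = state.occupancy
    ndim = occ.ndim
    grid = np.ascontiguousarray(occ if ndim == 2 else occ[None, :])
    mask = np.ascontiguousarray(
        state.irido_mask if ndim == 2 else state.irido_mask[None, :]
    )
    if params.h >= min(s for s in occ.shape) / 2 and ndim == 2:
        raise ValueError(
            f"h={params.h} too large for lattice {occ.shape}: require h < min(shape)/2"
        )

    prob = process_probabilities(params)
    cum = np.cumsum(prob)
    sr_dr, sr_dc = _short_range_offset_arrays(ndim)
    lr_dr, lr_dc = _long_range_offset_arrays(params, ndim, config.neighborhood)

    snap_every = config.snapshot_every or config.n_attempts
    n_snaps = config.n_attempts // snap_every
    snaps = np.zeros((n_snaps,) + grid.shape, dtype=np.int8)
    site_x = np.zeros(grid.shape, dtype=np.float64)
    site_m = np.zeros(grid.shape, dtype=np.float64)
    n_batches = 20
    batch_x = np.zeros(n_batches, dtype=np.float64)
    batch_m = np.zeros(n_batches, dtype=np.float64)

    _kmc_kernel(
        grid, mask, cum, sr_dr, sr_dc, lr_dr, lr_dc,
        int(config.n_attempts), int(config.seed), int(snap_every), snaps,
        int(config.burn_in), site_x, site_m, batch_x, batch_m,
    )

    n = grid.size
    measure = config.n_attempts - config.burn_in
    snapshots = []
    for i in range(n_snaps):
        t = (i + 1) * snap_every / n
        occ_i = snaps[i] if ndim == 2 else snaps[i][0]
        snapshots.append(
            (state.time + t, LatticeState(occ_i, state.irido_mask.copy(), state.time + t))
        )
    if not snapshots or config.n_attempts % snap_every != 0:
        t = config.n_attempts / n
        occ_f = grid if ndim == 2 else grid[0]
        snapshots.append(
            (state.time + t, LatticeState(occ_f.copy(), state.irido_mask.copy(), state.time + t))
        )

    per_batch = measure / n_batches
    traj = Trajectory(
        snapshots=snapshots,
        params=params,
        config=config,
        rng_provenance=f"numba-np.random(seed={config.seed})",
        site_x_mean=(site_x if ndim == 2 else site_x[0]) / measure,
        site_m_mean=(site_m if ndim == 2 else site_m[0]) / measure,
        batch_x=batch_x / (per_batch * n),
        batch_m=batch_m / (per_batch * n),
    )
    return traj


def with_irido_band(state: LatticeState, band_rows: Sequence[int]) -> LatticeState:
    """Return a copy of ``state`` whose iridophore mask is set on the given
    contiguous rows (melanophore birth forbidden there for the whole run)."""
    band_rows = sorted(int(r) for r in band_rows)
    if not band_rows:
        return state.copy()
    if state.occupancy.ndim != 2:
        raise ValueError("iridophore band requires a 2-D lattice")
    n_rows = state.occupancy.shape[0]
    if band_rows[0] < 0 or band_rows[-1] >= n_rows:
        raise ValueError(f"band rows {band_rows} out of range for {n_rows} rows")
    if band_rows != list(range(band_rows[0], band_rows[-1] + 1)):
        raise ValueError("band rows must be contiguous")
    out = state.copy()
    out.irido_mask[band_rows, :] = True
    if np.any(out.occupancy[out.irido_mask] == M):
        raise ValueError("cannot mask rows currently holding melanophores")
    return out
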