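"""Core model definitions: parameters, lattice state, neighborhoods, process catalogue.

The model describes a fish hypodermis as a square lattice whose nodes are
occupied by a xanthophore (X), a melanophore (M), or neither (S).  Cells are
strictly immobile; all dynamics comes from seven elementary birth/death
processes whose rates may depend on the occupancy of short-range (nearest
neighbor) or long-range (distance ``h``) sites.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "S",
    "X",
    "M",
    "ModelParams",
    "LatticeState",
    "ProcessKind",
    "PROCESS_RATE_ATTR",
    "short_range_neighbors",
    "long_range_neighbors",
    "ring_offsets",
    "read_config",
    "write_config",
]

# occupancy codes (values used in grids, CSV output and the CTMC oracle)
S, X, M = 0, 1, 2


class ProcessKind(enum.IntEnum):
    """The seven elementary stochastic processes of the scheme.

    Each entry maps to exactly one rate constant of :class:`ModelParams`.
    """

    X_BIRTH = 0            # S -> X at rate b_X
    M_BIRTH = 1            # S -> M at rate b_M (forbidden on masked nodes)
    X_DEATH = 2            # X -> S at rate d_X
    M_DEATH = 3            # M -> S at rate d_M
    X_KILLED_BY_M = 4      # X -> S at rate s_M, mediated by a nearest-neighbor M
    M_KILLED_BY_X = 5      # M -> S at rate s_X, mediated by a nearest-neighbor X
    M_BIRTH_LONGRANGE = 6  # S -> M at rate l_X, mediated by an X at distance h


#: rate-constant attribute of ModelParams backing each process
PROCESS_RATE_ATTR = {
    ProcessKind.X_BIRTH: "b_X",
    ProcessKind.M_BIRTH: "b_M",
    ProcessKind.X_DEATH: "d_X",
    ProcessKind.M_DEATH: "d_M",
    ProcessKind.X_KILLED_BY_M: "s_M",
    ProcessKind.M_KILLED_BY_X: "s_X",
    ProcessKind.M_BIRTH_LONGRANGE: "l_X",
}


@dataclass(frozen=True)
class ModelParams:
    """Rate constants and geometric parameters of the process scheme.

    Parameters
    ----------
    b_X, b_M : float
        Natural birth rates of xanthophores / melanophores (per site per
        unit time).
    d_X, d_M : float
        Natural death rates.
    s_M : float
        Rate at which a xanthophore dies due to an adjacent melanophore.
    s_X : float
        Rate at which a melanophore dies due to an adjacent xanthophore.
    l_X : float
        Long-range xanthophore-induced melanophore birth rate.
    h : int
        Long-range interaction distance in lattice units (``>= 2``).
    a : float
        Lattice spacing (length units), default 1.
    """

    b_X: float = 1.0
    b_M: float = 0.0
    d_X: float = 0.0
    d_M: float = 0.0
    s_X: float = 1.0
    s_M: float = 1.0
    l_X: float = 2.5
    h: int = 16
    a: float = 1.0

    def __post_init__(self) -> None:
        for name in ("b_X", "b_M", "d_X", "d_M", "s_X", "s_M", "l_X"):
            if getattr(self, name) < 0:
                raise ValueError(f"rate constant {name} must be >= 0")
        if self.h < 2:
            raise ValueError("interaction distance h must be an integer >= 2")
        if self.a <= 0:
            raise ValueError("lattice spacing a must be > 0")

    @property
    def rates(self) -> np.ndarray:
        """Rate constants ordered by :class:`ProcessKind`."""
        return np.array(
            [getattr(self, PROCESS_RATE_ATTR[k]) for k in ProcessKind], dtype=float
        )

    @property
    def is_simplified_regime(self) -> bool:
        """True iff d_X = d_M = b_M = 0 and s_X = s_M (the regime used for
        all closed-form analysis)."""
        return (
            self.d_X == 0.0
            and self.d_M == 0.0
            and self.b_M == 0.0
            and self.s_X == self.s_M
        )

    def replace(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)


@dataclass
class LatticeState:
    """Occupancy grid plus the static iridophore mask.

    ``occupancy`` holds one code per node (0=S, 1=X, 2=M); it is 1-D of
    length N for a ring or 2-D of shape (rows, cols) for a torus.  Nodes
    where ``irido_mask`` is true can never hold a melanophore (the mask
    models a band of iridophores that forbids melanophore birth).
    """

    occupancy: np.ndarray
    irido_mask: np.ndarray | None = None
    time: float = 0.0

    def __post_init__(self) -> None:
        self.occupancy = np.asarray(self.occupancy, dtype=np.int8)
        if self.occupancy.ndim not in (1, 2):
            raise ValueError("occupancy must be 1-D or 2-D")
        if self.irido_mask is None:
            self.irido_mask = np.zeros(self.occupancy.shape, dtype=bool)
        else:
            self.irido_mask = np.asarray(self.irido_mask, dtype=bool)
            if self.irido_mask.shape != self.occupancy.shape:
                raise ValueError("mask shape must match occupancy shape")
        self.validate()

    @classmethod
    def all_s(cls, shape: int | tuple[int, int]) -> "LatticeState":
        """Uniform empty lattice (the default initial condition)."""
        if isinstance(shape, int):
            shape = (shape,)
        return cls(np.zeros(shape, dtype=np.int8))

    @property
    def shape(self) -> tuple[int, ...]:
        return self.occupancy.shape

    @property
    def n_sites(self) -> int:
        return self.occupancy.size

    def coverage(self) -> tuple[float, float, float]:
        """Fractions of nodes in (S, X, M)."""
        n = self.n_sites
        return (
            float(np.count_nonzero(self.occupancy == S)) / n,
            float(np.count_nonzero(self.occupancy == X)) / n,
            float(np.count_nonzero(self.occupancy == M)) / n,
        )

    def validate(self) -> None:
        if not np.isin(self.occupancy, (S, X, M)).all():
            raise ValueError("occupancy codes must be in {0, 1, 2}")
        if np.any(self.occupancy[self.irido_mask] == M):
            raise ValueError("masked (iridophore) node holds a melanophore")

    def copy(self) -> "LatticeState":
        return LatticeState(
            self.occupancy.copy(), self.irido_mask.copy(), self.time
        )


# ---------------------------------------------------------------------------
# neighborhoods
# ---------------------------------------------------------------------------

def _check_site(site, shape) -> tuple:
    if isinstance(site, (int, np.integer)):
        site = (int(site),)
    site = tuple(int(c) for c in site)
    if len(site) != len(shape):
        raise ValueError(f"site {site} does not match lattice dimension {len(shape)}")
    for c, n in zip(site, shape):
        if not 0 <= c < n:
            raise ValueError(f"site {site} outside lattice of shape {shape}")
    return site


def short_range_neighbors(site, shape) -> list:
    """First neighbors of ``site`` under periodic boundaries.

    Returns the 2 sites at +-1 on a ring, or the 4 von Neumann neighbors on
    a torus.  2-D sites are (column, row) pairs against a (width, height)
    shape.
    """
    shape = tuple(int(n) for n in shape)
    site = _check_site(site, shape)
    if len(shape) == 1:
        (i,), (n,) = site, shape
        out = [((i - 1) % n,), ((i + 1) % n,)]
        return [s[0] for s in out]
    (cx, cy), (w, h) = site, shape
    return [
        ((cx - 1) % w, cy),
        ((cx + 1) % w, cy),
        (cx, (cy - 1) % h),
        (cx, (cy + 1) % h),
    ]


def ring_offsets(h: int) -> np.ndarray:
    """Integer (dx, dy) offsets whose Euclidean length d satisfies
    ``|d - h| < 0.5`` — a one-cell-wide ring of radius h."""
    if h < 2:
        raise ValueError("h must be >= 2")
    rng = np.arange(-h - 1, h + 2)
    dx, dy = np.meshgrid(rng, rng, indexing="ij")
    d = np.hypot(dx, dy)
    sel = np.abs(d - h) < 0.5
    return np.stack([dx[sel], dy[sel]], axis=1)


def long_range_neighbors(site, shape, h: int) -> list:
    """Sites at long-range distance ``h`` from ``site`` (periodic metric).

    On a ring this is exactly ``{site - h, site + h}``; on a torus it is the
    one-cell-wide Euclidean ring of radius h.  Requires ``h < min(shape)/2``
    so the ring does not overlap itself through the periodic wrap.
    """
    shape = tuple(int(n) for n in shape)
    site = _check_site(site, shape)
    if h < 2:
        raise ValueError("h must be >= 2")
    if h >= min(shape) / 2:
        raise ValueError(
            f"h={h} too large for lattice {shape}: require h < min(shape)/2 "
            "so the periodic ring does not self-overlap"
        )
    if len(shape) == 1:
        (i,), (n,) = site, shape
        return sorted({(i - h) % n, (i + h) % n})
    (cx, cy), (w, hh) = site, shape
    return sorted(
        ((cx + dx) % w, (cy + dy) % hh) for dx, dy in ring_offsets(h)
    )


def axes_offsets(h: int) -> np.ndarray:
    """The 4 axis-aligned offsets at distance h (alternative long-range
    neighborhood, for sensitivity checks)."""
    if h < 2:
        raise ValueError("h must be >= 2")
    return np.array([(h, 0), (-h, 0), (0, h), (0, -h)])


# ---------------------------------------------------------------------------
# plain-text configuration files
# ---------------------------------------------------------------------------

_CONFIG_KEYS = {
    "b_X": float, "b_M": float, "d_X": float, "d_M": float,
    "s_X": float, "s_M": float, "l_X": float, "h": int, "a": float,
    "width": int, "height": int, "seed": int, "steps": int,
    "snapshot_every": int, "irido_band_rows": int, "neighborhood": str,
}


def read_config(path: str | Path) -> dict:
    """Parse a ``key=value`` config file (``#`` starts a comment)."""
    out: dict = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected key=value, got {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        if key not in _CONFIG_KEYS:
            raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
        out[key] = _CONFIG_KEYS[key](value)
    if out.get("neighborhood", "ring") not in ("ring", "axes"):
        raise ValueError("neighborhood must be 'ring' or 'axes'")
    return out


def write_config(path: str | Path, values: dict) -> None:
    lines = [f"{k} = {v}" for k, v in values.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def params_from_config(cfg: dict) -> ModelParams:
    """Build :class:`ModelParams` from a parsed config dict."""
    fields = {k: v for k, v in cfg.items()
              if k in ("b_X", "b_M", "d_X", "d_M", "s_X", "s_M", "l_X", "h", "a")}
    return ModelParams(**fields)
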