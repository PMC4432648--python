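"""Quantification of simulated patterns.

Provides the radially averaged structure factor (spectral wavelength
estimator), coverage-based morphology classification (spots / stripes /
homogeneous), stripe-orientation anisotropy for pre-pattern experiments,
and synthetic fixture grids (planted stripes, spots, noise) for testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .model import M, S, X, LatticeState

__all__ = [
    "SpectrumReport",
    "MorphologyReport",
    "structure_factor",
    "classify_morphology",
    "orientation_anisotropy",
    "make_stripes",
    "make_spots",
    "make_noise",
]


@dataclass
class SpectrumReport:
    """Radially averaged power spectrum of the melanophore field."""

    k_bins: np.ndarray          # bin centers (1/length)
    power: np.ndarray           # radially averaged power per bin
    counts: np.ndarray          # Fourier modes per bin
    total_power: float          # sum over all modes = field variance (Parseval)
    peak_k: float               # argmax over bins excluding k = 0
    peak_wavelength: float      # 2*pi / peak_k
    peak_significance: float    # peak power / median power


@dataclass
class ComponentStats:
    n_components: int
    mean_elongation: float      # size-weighted; inf if any component percolates
    any_percolating: bool
    sizes: list = field(default_factory=list)


@dataclass
class MorphologyReport:
    m_coverage: float
    x_coverage: float
    label: str                  # HOMOGENEOUS_X | M_SPOTS | STRIPES | X_SPOTS | HOMOGENEOUS_M
    component_stats: dict       # {"M": ComponentStats, "X": ComponentStats}
    anisotropy: float
    warnings: list = field(default_factory=list)


def _m_field(state) -> np.ndarray:
    """Mean-subtracted real field to analyse: the M-indicator of a
    LatticeState, or any float array given directly."""
    if isinstance(state, LatticeState):
        f = (state.occupancy == M).astype(float)
    else:
        f = np.asarray(state, dtype=float)
    return f - f.mean()


def structure_factor(state, a: float = 1.0) -> SpectrumReport:
    """Radially averaged power spectrum of the (centered) M field.

    Power is normalised so the total over all modes equals the field
    variance; annular bins have width 2*pi/(max(W,H)*a) and the peak bin is
    refined by quadratic interpolation.  A constant field yields
    ``peak_significance = 0`` and no peak claim (NaN peak).
    """
    f = _m_field(state)
    if f.ndim == 1:
        F = np.fft.fft(f)
        P = np.abs(F) ** 2 / f.size**2
        k = 2 * math.pi * np.abs(np.fft.fftfreq(f.size, d=a))
        width = 2 * math.pi / (f.size * a)
    elif f.ndim == 2:
        F = np.fft.fft2(f)
        P = np.abs(F) ** 2 / f.size**2
        ky = 2 * math.pi * np.fft.fftfreq(f.shape[0], d=a)
        kx = 2 * math.pi * np.fft.fftfreq(f.shape[1], d=a)
        k = np.hypot(*np.meshgrid(ky, kx, indexing="ij"))
        width = 2 * math.pi / (max(f.shape) * a)
    else:
        raise ValueError("state must be 1-D or 2-D")

    idx = np.rint(k / width).astype(int).ravel()
    n_bins = idx.max() + 1
    sums = np.bincount(idx, weights=P.ravel(), minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        avg = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    k_bins = np.arange(n_bins) * width
    total = float(P.sum())

    if total < 1e-14:  # degenerate all-equal field
        return SpectrumReport(k_bins, avg, counts, total, float("nan"),
                              float("nan"), 0.0)

    body = avg[1:]
    j = 1 + int(np.argmax(body))
    peak_k = k_bins[j]
    # quadratic interpolation around the peak bin
    if 1 <= j - 1 and j + 1 < n_bins and counts[j - 1] > 0 and counts[j + 1] > 0:
        y0, y1, y2 = avg[j - 1], avg[j], avg[j + 1]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            peak_k = k_bins[j] + 0.5 * width * (y0 - y2) / denom
    med = float(np.median(body[counts[1:] > 0]))
    significance = float(avg[j] / med) if med > 0 else float("inf")
    return SpectrumReport(k_bins, avg, counts, total, float(peak_k),
                          2 * math.pi / float(peak_k), significance)


# ---------------------------------------------------------------------------
# connected components on the torus
# ---------------------------------------------------------------------------

def _torus_components(binary: np.ndarray) -> list[np.ndarray]:
    """4-connected components of a boolean 2-D field with periodic wrap;
    returns one (n_pixels, 2) coordinate array per component."""
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    lab, n = ndimage.label(binary, structure=structure)
    if n == 0:
        return []
    parent = list(range(n + 1))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    rows, cols = binary.shape
    for c in range(cols):
        if binary[0, c] and binary[-1, c]:
            union(lab[0, c], lab[-1, c])
    for r in range(rows):
        if binary[r, 0] and binary[r, -1]:
            union(lab[r, 0], lab[r, -1])

    groups: dict[int, list[int]] = {}
    flat = lab.ravel()
    for i in np.nonzero(flat)[0]:
        groups.setdefault(find(flat[i]), []).append(i)
    out = []
    for idxs in groups.values():
        idxs = np.asarray(idxs)
        out.append(np.stack([idxs // cols, idxs % cols], axis=1))
    return out


def _component_geometry(coords: np.ndarray, shape: tuple[int, int]):
    """(elongation, percolates_axis0, percolates_axis1) of one component.

    Percolation = the component occupies every index of an axis (spans a
    full period).  Non-percolating components are unwrapped through the
    periodic boundary before the second-moment ellipse is computed;
    percolating ones get infinite elongation.
    """
    perc = []
    unwrapped = coords.astype(float).copy()
    for ax, L in enumerate(shape):
        present = np.zeros(L, dtype=bool)
        present[coords[:, ax]] = True
        if present.all():
            perc.append(True)
            continue
        perc.append(False)
        gap = int(np.nonzero(~present)[0][0])
        unwrapped[:, ax] = (coords[:, ax] - gap - 1) % L
    if any(perc):
        return float("inf"), perc[0], perc[1]
    # second-moment ellipse; 1/12 is the variance of a unit pixel
    cov = np.cov(unwrapped.T) if len(coords) > 1 else np.zeros((2, 2))
    cov = np.atleast_2d(cov) + np.eye(2) / 12.0
    ev = np.linalg.eigvalsh(cov)
    return float(math.sqrt(ev[1] / ev[0])), perc[0], perc[1]


def _phase_stats(binary: np.ndarray, min_size: int = 4) -> ComponentStats:
    comps = _torus_components(binary)
    sizes = [len(c) for c in comps]
    elong, weights, any_perc = [], [], False
    for c in comps:
        if len(c) < min_size:
            continue
        e, p0, p1 = _component_geometry(c, binary.shape)
        any_perc = any_perc or p0 or p1
        elong.append(e)
        weights.append(len(c))
    if any_perc or any(math.isinf(e) for e in elong):
        mean_e = float("inf")
    elif elong:
        mean_e = float(np.average(elong, weights=weights))
    else:
        mean_e = 1.0
    return ComponentStats(len(comps), mean_e, any_perc, sizes)


def classify_morphology(
    state: LatticeState,
    coverage_threshold: float = 0.02,
    elongation_threshold: float = 2.0,
    stationary: bool | None = None,
) -> MorphologyReport:
    """Rule-based morphology label of a (stationary) snapshot.

    HOMOGENEOUS_X / HOMOGENEOUS_M when the other phase covers < 2% of the
    lattice; otherwise the minority chromatophore phase decides: compact,
    non-percolating domains (size-weighted mean elongation below 2) give
    spots of that phase, elongated or percolating domains give STRIPES.
    Thresholds are package choices, exposed as arguments.
    """
    if state.occupancy.ndim != 2:
        raise ValueError("morphology classification requires a 2-D state")
    _, x_cov, m_cov = state.coverage()
    warnings = []
    if stationary is False:
        warnings.append("snapshot flagged non-stationary by the caller")

    stats = {
        "M": _phase_stats(state.occupancy == M),
        "X": _phase_stats(state.occupancy == X),
    }
    aniso = orientation_anisotropy(state)

    if m_cov < coverage_threshold:
        label = "HOMOGENEOUS_X"
    elif x_cov < coverage_threshold:
        label = "HOMOGENEOUS_M"
    else:
        minority = "M" if m_cov <= x_cov else "X"
        st = stats[minority]
        if st.any_percolating or st.mean_elongation >= elongation_threshold:
            label = "STRIPES"
        else:
            label = "M_SPOTS" if minority == "M" else "X_SPOTS"
    return MorphologyReport(m_coverage=m_cov, x_coverage=x_cov, label=label,
                            component_stats=stats, anisotropy=aniso,
                            warnings=warnings)


def orientation_anisotropy(state, sector_deg: float = 15.0, a: float = 1.0) -> float:
    """Spectral power within +-15 deg of the vertical k-axis over that
    within +-15 deg of the horizontal k-axis; > 1 indicates horizontal
    stripes (variation along rows)."""
    f = _m_field(state)
    if f.ndim != 2:
        raise ValueError("orientation anisotropy requires a 2-D state")
    P = np.abs(np.fft.fft2(f)) ** 2 / f.size**2
    ky = 2 * math.pi * np.fft.fftfreq(f.shape[0], d=a)
    kx = 2 * math.pi * np.fft.fftfreq(f.shape[1], d=a)
    KY, KX = np.meshgrid(ky, kx, indexing="ij")
    knorm = np.hypot(KY, KX)
    theta = np.arctan2(np.abs(KY), np.abs(KX))  # 0 = horizontal axis of k-space
    sector = math.radians(sector_deg)
    nonzero = knorm > 0
    vert = P[nonzero & (theta >= math.pi / 2 - sector)].sum()
    horiz = P[nonzero & (theta <= sector)].sum()
    if horiz == 0 and vert == 0:
        return 1.0
    if horiz == 0:
        return float("inf")
    return float(vert / horiz)


# ---------------------------------------------------------------------------
# fixture generators (planted patterns for testing the estimators)
# ---------------------------------------------------------------------------

def make_stripes(period: int, shape: tuple[int, int] = (64, 64),
                 orientation: str = "horizontal", phase: float = 0.0) -> LatticeState:
    """Binary stripes of M on X with the given period (cells)."""
    rows, cols = shape
    y = np.arange(rows)[:, None] if orientation == "horizontal" else np.arange(cols)[None, :]
    wave = np.sin(2 * math.pi * y / period + phase)
    occ = np.where(np.broadcast_to(wave >= 0, shape), M, X).astype(np.int8)
    return LatticeState(occ)


def make_spots(spacing: int, radius: float, shape: tuple[int, int] = (64, 64),
               invert: bool = False) -> LatticeState:
    """Grid of compact disks of M on an X background (X spots if invert)."""
    rows, cols = shape
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    inside = np.zeros(shape, dtype=bool)
    for cy in range(spacing // 2, rows, spacing):
        for cx in range(spacing // 2, cols, spacing):
            dy = np.minimum(np.abs(rr - cy), rows - np.abs(rr - cy))
            dx = np.minimum(np.abs(cc - cx), cols - np.abs(cc - cx))
            inside |= dy * dy + dx * dx <= radius * radius
    fg, bg = (X, M) if invert else (M, X)
    occ = np.where(inside, fg, bg).astype(np.int8)
    return LatticeState(occ)


def make_noise(shape: tuple[int, int] = (64, 64), p_m: float = 0.5,
               seed: int = 0) -> LatticeState:
    """I.i.d. random M/X field (no intrinsic wavelength)."""
    rng = np.random.default_rng(seed)
    occ = np.where(rng.random(shape) < p_m, M, X).astype(np.int8)
    return LatticeState(occ)
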