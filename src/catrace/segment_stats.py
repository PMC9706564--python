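"""Binned angle distributions, potentials of mean force, covariance maps.

Histograms use the survey's bin widths (10 deg in theta, 20 deg in gamma).
Dihedral axes are binned either centered, on [-180, 180), or positive, on
[0, 360) -- the positive range avoids splitting helical-distribution maxima
that sit near 0/360.  The potential of mean force over the wrapped dihedral
sum Gamma is the dimensionless F_i = -ln(N_i / N_tot), shifted so the
occupied minimum is zero; empty bins stay masked rather than infinite.
The per-bin covariance map is c_ij = P_ij - P_i P_j, with the marginals
taken from the same grid, so it sums to zero exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .virtual_geometry import wrap_deg

__all__ = [
    "HistGrid",
    "hist2d",
    "hist1d",
    "marginals",
    "pmf_of_sum",
    "PmfProfile",
    "covariance_map",
    "theta_gamma_grid",
    "circular_covariance",
    "circular_covariance_se",
    "effective_sample_size",
    "mcmc_circular_covariance_se",
]


@dataclass
class HistGrid:
    """A 1-D or 2-D binned angle distribution (uniform, half-open bins)."""

    edges: list            # one degree array per axis
    counts: np.ndarray     # integer counts, shape matches edges

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        self.edges = [np.asarray(e, float) for e in self.edges]

    @property
    def dims(self) -> int:
        return self.counts.ndim

    @property
    def N_tot(self) -> int:
        return int(self.counts.sum())

    @property
    def probabilities(self) -> np.ndarray:
        """counts / N_tot; all-NaN when the grid is empty."""
        if self.N_tot == 0:
            return np.full(self.counts.shape, np.nan)
        return self.counts / self.N_tot

    @property
    def centers(self) -> list:
        return [0.5 * (e[1:] + e[:-1]) for e in self.edges]


def _wrap_for_mode(x, range_mode: str) -> np.ndarray:
    x = np.asarray(x, float)
    if range_mode == "centered":
        return np.mod(x + 180.0, 360.0) - 180.0      # [-180, 180)
    if range_mode == "positive":
        return np.mod(x, 360.0)                      # [0, 360)
    raise ValueError("range_mode must be 'centered' or 'positive'")


def _gamma_edges(binwidth: float, range_mode: str) -> np.ndarray:
    if 360.0 % binwidth:
        raise ValueError("binwidth must divide 360")
    lo = -180.0 if range_mode == "centered" else 0.0
    return np.arange(lo, lo + 360.0 + binwidth / 2, binwidth)


def hist2d(x, y, binwidth: float = 20.0,
           range_mode: str = "centered") -> HistGrid:
    """2-D histogram of two angle lists on a uniform wrapped grid."""
    xs = _wrap_for_mode(x, range_mode)
    ys = _wrap_for_mode(y, range_mode)
    if len(xs) != len(ys):
        raise ValueError("x and y must have equal length")
    edges = _gamma_edges(binwidth, range_mode)
    counts, _, _ = np.histogram2d(xs, ys, bins=[edges, edges])
    return HistGrid(edges=[edges, edges], counts=counts.astype(int))


def hist1d(x, binwidth: float = 20.0, range_mode: str = "centered") -> HistGrid:
    xs = _wrap_for_mode(x, range_mode)
    edges = _gamma_edges(binwidth, range_mode)
    counts, _ = np.histogram(xs, bins=edges)
    return HistGrid(edges=[edges], counts=counts.astype(int))


def marginals(grid: HistGrid) -> tuple[HistGrid, HistGrid]:
    """Row and column marginals of a 2-D grid as 1-D grids."""
    if grid.dims != 2:
        raise ValueError("marginals need a 2-D grid")
    gx = HistGrid(edges=[grid.edges[0]], counts=grid.counts.sum(axis=1))
    gy = HistGrid(edges=[grid.edges[1]], counts=grid.counts.sum(axis=0))
    return gx, gy


@dataclass
class PmfProfile:
    """Dimensionless PMF over binned Gamma; F is NaN on empty bins."""

    centers: np.ndarray
    counts: np.ndarray
    F: np.ndarray

    @property
    def occupied(self) -> np.ndarray:
        return self.counts > 0


def pmf_of_sum(gamma_sums, binwidth: float = 20.0) -> PmfProfile:
    """PMF F_i = -ln(N_i / N_tot) over wrapped dihedral sums, shifted so
    min F = 0 over occupied bins; empty bins masked (NaN), never infinite."""
    g = wrap_deg(np.asarray(gamma_sums, float))
    grid = hist1d(g, binwidth=binwidth, range_mode="centered")
    if grid.N_tot == 0:
        raise ValueError("pmf_of_sum needs at least one sample")
    counts = grid.counts.astype(float)
    F = np.full(len(counts), np.nan)
    occ = counts > 0
    F[occ] = -np.log(counts[occ] / grid.N_tot)
    F[occ] -= F[occ].min()
    return PmfProfile(centers=grid.centers[0], counts=grid.counts, F=F)


def covariance_map(grid: HistGrid) -> np.ndarray:
    """Per-bin association c_ij = P_ij - P_i P_j (sums to zero exactly)."""
    if grid.dims != 2:
        raise ValueError("covariance_map needs a 2-D grid")
    if grid.N_tot == 0:
        raise ValueError("covariance_map needs a populated grid")
    P = grid.probabilities
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    return P - np.outer(px, py)


def theta_gamma_grid(segments, end: str = "N",
                     theta_binwidth: float = 10.0,
                     gamma_binwidth: float = 20.0) -> HistGrid:
    """2-D histogram of a terminal theta against its adjacent terminal
    gamma over a segment list (theta on [0, 180), gamma centered)."""
    if end == "N":
        th = np.array([s.theta_N for s in segments], float)
        ga = np.array([s.gamma_N for s in segments], float)
    elif end == "C":
        th = np.array([s.theta_C for s in segments], float)
        ga = np.array([s.gamma_C for s in segments], float)
    else:
        raise ValueError("end must be 'N' or 'C'")
    t_edges = np.arange(0.0, 180.0 + theta_binwidth / 2, theta_binwidth)
    g_edges = _gamma_edges(gamma_binwidth, "centered")
    if len(th) == 0:
        counts = np.zeros((len(t_edges) - 1, len(g_edges) - 1), int)
    else:
        ga = _wrap_for_mode(ga, "centered")
        counts, _, _ = np.histogram2d(th, ga, bins=[t_edges, g_edges])
        counts = counts.astype(int)
    return HistGrid(edges=[t_edges, g_edges], counts=counts)


def circular_covariance(x, y) -> float:
    """Scalar circular covariance mean(sin(x - mx) sin(y - my)) with mx, my
    the circular means; a compact diagnostic of the sign of association
    between two wrapped angles (negative = anticorrelated)."""
    xr = np.radians(np.asarray(x, float))
    yr = np.radians(np.asarray(y, float))
    mx = np.arctan2(np.sin(xr).mean(), np.cos(xr).mean())
    my = np.arctan2(np.sin(yr).mean(), np.cos(yr).mean())
    return float(np.mean(np.sin(xr - mx) * np.sin(yr - my)))


def circular_covariance_se(x, y) -> float:
    """Standard error of circular_covariance (sample SD of the per-pair
    products over sqrt(n))."""
    xr = np.radians(np.asarray(x, float))
    yr = np.radians(np.asarray(y, float))
    mx = np.arctan2(np.sin(xr).mean(), np.cos(xr).mean())
    my = np.arctan2(np.sin(yr).mean(), np.cos(yr).mean())
    prod = np.sin(xr - mx) * np.sin(yr - my)
    return float(prod.std(ddof=1) / np.sqrt(len(prod)))


def effective_sample_size(series) -> float:
    """Effective sample size of a (possibly thinned) Markov-chain series
    from its lag-1 autocorrelation, n (1 - rho) / (1 + rho)."""
    x = np.asarray(series, float)
    x = x - x.mean()
    denom = float(np.dot(x, x))
    if denom == 0.0:
        return float(len(x))
    rho = float(np.dot(x[:-1], x[1:]) / denom)
    rho = min(max(rho, 0.0), 0.999)
    return len(x) * (1 - rho) / (1 + rho)


def mcmc_circular_covariance_se(x, y) -> float:
    """Standard error of circular_covariance for autocorrelated (MCMC)
    draws: the i.i.d. SE inflated by the effective sample size of the
    per-pair product series."""
    xr = np.radians(np.asarray(x, float))
    yr = np.radians(np.asarray(y, float))
    mx = np.arctan2(np.sin(xr).mean(), np.cos(xr).mean())
    my = np.arctan2(np.sin(yr).mean(), np.cos(yr).mean())
    prod = np.sin(xr - mx) * np.sin(yr - my)
    return float(prod.std(ddof=1) / np.sqrt(effective_sample_size(prod)))
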