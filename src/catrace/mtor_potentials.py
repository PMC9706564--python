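"""Multitorsional potentials over consecutive virtual-bond dihedrals.

The correlation part of the potential of mean force of a C-alpha trace
couples n >= 2 consecutive dihedrals gamma through a weighted sum of
cosines of their +/-1 linear combinations.  The weights are sin(theta) at
the two window ends and (1 -+ cos(theta)) factors for the inner vertices,
so the term self-gates on backbone shape:

* extended interior (inner theta -> 180): the all-plus combination
  dominates and the potential collapses to a function of the *sum* of the
  gamma angles alone (the mechanism behind concerted, anticorrelated
  changes of the terminal dihedrals of a strand bordered by turns);
* right-angle interior (theta = 90): all combinations carry equal weight
  and the sum reduces to a product of single-angle cosines, i.e. the
  dihedrals decouple (the helical regime).

Energies are dimensionless (multiples of RT).  All angles in degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np

__all__ = [
    "WindowAngles",
    "MtorParams",
    "dominant_weight",
    "u_generic",
    "u_ext",
    "u_fold",
    "u_total",
    "sign_vectors",
]


@dataclass
class WindowAngles:
    """Angles of one (k, n) window: n dihedrals, n + 3 atoms, hence two
    terminal virtual-bond angles and n - 1 inner ones."""

    theta_first: float
    theta_last: float
    theta_inner: np.ndarray
    gamma: np.ndarray

    def __post_init__(self):
        self.theta_inner = np.atleast_1d(np.asarray(self.theta_inner, float))
        self.gamma = np.atleast_1d(np.asarray(self.gamma, float))
        if len(self.gamma) < 2:
            raise ValueError("window needs at least 2 dihedrals")
        if len(self.theta_inner) != len(self.gamma) - 1:
            raise ValueError(
                f"n={len(self.gamma)} dihedrals require n-1 inner theta, "
                f"got {len(self.theta_inner)}"
            )

    @property
    def n(self) -> int:
        return len(self.gamma)


@dataclass
class MtorParams:
    """Adjustable parameters of the extended/folded force-field terms.

    a[M-1], b[M-1] -- Fourier coefficients over multiplicity M = 1..M_max
                      for the extended and folded terms (dimensionless);
    phi, psi       -- phase angles per dihedral position, degrees (None =
                      all zero; symmetric units have phases 0 or 180);
    n_max          -- longest window (dihedral count) included in u_total.
    """

    a: np.ndarray = field(default_factory=lambda: np.array([1.0]))
    b: np.ndarray = field(default_factory=lambda: np.array([1.0]))
    phi: np.ndarray | None = None
    psi: np.ndarray | None = None
    n_max: int = 5

    def __post_init__(self):
        self.a = np.atleast_1d(np.asarray(self.a, float))
        self.b = np.atleast_1d(np.asarray(self.b, float))
        if self.n_max < 2:
            raise ValueError("n_max must be >= 2")


def _phases(phase, n: int) -> np.ndarray:
    if phase is None:
        return np.zeros(n)
    p = np.atleast_1d(np.asarray(phase, float))
    if p.size == 1:
        return np.full(n, p[0])
    if len(p) < n:
        raise ValueError(f"need {n} phase angles, got {len(p)}")
    return p[:n]


def dominant_weight(w: WindowAngles) -> float:
    """Weight of the dominant (all-plus) cosine term of the generic
    multitorsional expansion:

        sin(theta_first) * sin(theta_last) * prod_j (1 - cos theta_inner_j)/2

    It equals 1 exactly when both terminal angles are 90 deg and every
    inner angle is 180 deg (the turn-bordered extended limit) and tends to
    0 as a window end straightens.
    """
    tf, tl = np.radians(w.theta_first), np.radians(w.theta_last)
    ti = np.radians(w.theta_inner)
    return float(np.sin(tf) * np.sin(tl) * np.prod((1.0 - np.cos(ti)) / 2.0))


def sign_vectors(n: int) -> np.ndarray:
    """The 2^(n-1) sign vectors s in {+1, -1}^(n-1), all-plus first
    (lexicographic with +1 before -1); fixes the ordering of sign_coeffs."""
    return np.array(list(product((1, -1), repeat=n - 1)), dtype=float)


def u_generic(w: WindowAngles, phases=None, sign_coeffs=None) -> float:
    """Generic multitorsional term for an n-dihedral window:

        U = 2^-(n-1) sin(tf) sin(tl)
            * sum_s C_s prod_j (1 - s_j cos ti_j)
                    * cos((g_1 + p_1) + sum_j s_j (g_{j+1} + p_{j+1}))

    with the sum over sign vectors s in {+1,-1}^(n-1).  The (1 - cos) /
    (1 + cos) pairing puts the all-plus branch in charge as the interior
    straightens, so the theta->180 limit is a single cosine of the summed
    dihedrals, while at all-90-degree theta every branch has weight 1 and
    the sum telescopes (cos(x+y) + cos(x-y) = 2 cos x cos y) into a product
    of single-angle cosines.
    """
    n = w.n
    p = _phases(phases, n)
    svecs = sign_vectors(n)
    if sign_coeffs is None:
        coeffs = np.ones(len(svecs))
    else:
        coeffs = np.asarray(sign_coeffs, float)
        if len(coeffs) != len(svecs):
            raise ValueError(f"need {len(svecs)} sign coefficients")
    g = np.radians(w.gamma + p)
    ct = np.cos(np.radians(w.theta_inner))
    weights = np.prod(1.0 - svecs * ct[None, :], axis=1)
    args = g[0] + svecs @ g[1:]
    total = float(np.sum(coeffs * weights * np.cos(args)))
    tf, tl = np.radians(w.theta_first), np.radians(w.theta_last)
    return float(2.0 ** -(n - 1) * np.sin(tf) * np.sin(tl) * total)


def u_ext(w: WindowAngles, p: MtorParams) -> float:
    """Extended-segment force-field term.  With Gamma_w = sum_j (gamma_j +
    phi_j),

        U_e = sin(tf) sin(tl) prod_j (1 - cos ti_j)/2
              * sum_{M=1}^{M_max} a_M cos(M * Gamma_w)

    It depends on the dihedrals only through their sum, so any concerted
    change leaving Gamma_w fixed is free; the weight gates the term onto
    turn-bordered extended interiors.
    """
    phi = _phases(p.phi, w.n)
    gw = np.radians(np.sum(w.gamma + phi))
    m = np.arange(1, len(p.a) + 1)
    return dominant_weight(w) * float(np.sum(p.a * np.cos(m * gw)))


def u_fold(w: WindowAngles, p: MtorParams) -> float:
    """Folded-segment force-field term:

        U_f = prod_j sin^2(ti_j)
              * sum_{M=1}^{M_max} b_M prod_{j=1}^{n} cos(M (gamma_j + psi_j))

    Separable in the individual dihedrals (no cross-gamma coupling); the
    sin^2 gate confines it to interiors near 90 degrees (helical shape).
    """
    psi = _phases(p.psi, w.n)
    gate = float(np.prod(np.sin(np.radians(w.theta_inner)) ** 2))
    g = np.radians(w.gamma + psi)
    m = np.arange(1, len(p.b) + 1)
    terms = np.prod(np.cos(np.outer(m, g)), axis=1)
    return gate * float(np.sum(p.b * terms))


def u_total(geom, p: MtorParams, flagged_bonds=None) -> float:
    """Full multitorsional energy of a chain: sum of u_ext + u_fold over
    every window of n = 2..n_max dihedrals that lies fully inside the
    chain, has all angles defined, and crosses no flagged bond.

    ``geom`` is a VirtualGeometry; ``flagged_bonds``, if given, is a boolean
    sequence over bonds 1..nres-1 (1-based padded or length nres-1) marking
    cis/break bonds that windows must not cross.
    """
    nres = geom.nres
    flags = None
    if flagged_bonds is not None:
        fb = np.asarray(flagged_bonds, bool)
        flags = np.zeros(nres + 1, bool)
        if len(fb) == nres - 1:
            flags[1:nres] = fb
        elif len(fb) == nres + 1:
            flags = fb
        else:
            raise ValueError("flagged_bonds must cover bonds 1..nres-1")
    total = 0.0
    for n in range(2, p.n_max + 1):
        for k in range(1, nres - n - 1):
            if flags is not None and np.any(flags[k : k + n + 2]):
                continue
            tf, tl, ti = geom.theta_window(k, n)
            g = geom.gamma_window(k, n)
            if np.any(np.isnan(g)) or np.any(np.isnan(ti)) or np.isnan(tf) or np.isnan(tl):
                continue
            w = WindowAngles(tf, tl, ti, g)
            total += u_ext(w, p) + u_fold(w, p)
    return total
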