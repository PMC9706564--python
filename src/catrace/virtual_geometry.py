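"""Virtual-bond internal coordinates of a C-alpha trace.

A polypeptide backbone reduced to its C-alpha atoms is described by the
virtual-bond lengths d_i (bond i joins atoms i and i+1, ~3.8 A for trans
peptide groups), the virtual-bond angles theta_i (vertex at atom i, defined
for i = 2..nres-1) and the virtual-bond dihedral angles gamma_i (rotation
about the i -> i+1 bond, defined for i = 2..nres-2).  Indexing is 1-based
throughout, matching the conventional labelling of the trace; arrays are
padded so that ``geom.theta[i]`` is theta_i directly.

All angles are handled in degrees externally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DegenerateGeometryError",
    "VirtualGeometry",
    "wrap_deg",
    "compute_geometry",
    "gamma_sum",
    "rebuild_chain",
    "axis_dihedral",
]


class DegenerateGeometryError(ValueError):
    """Raised when coordinates do not define the requested internal angle."""


def wrap_deg(x):
    """Wrap an angle (degrees) into the half-open interval (-180, 180].

    The upper end is closed: wrap_deg(-180) == wrap_deg(180) == 180.
    Accepts scalars or arrays.
    """
    return 180.0 - np.mod(180.0 - np.asarray(x, dtype=float), 360.0)


@dataclass
class VirtualGeometry:
    """Internal coordinates of one C-alpha trace, 1-based padded arrays.

    theta[i]       -- virtual-bond angle at vertex i, valid for 2 <= i <= nres-1
    gamma[i]       -- dihedral about bond i -> i+1, valid for 2 <= i <= nres-2;
                      NaN where a collinear triple leaves it undefined
    bond_length[i] -- length of bond i (atoms i, i+1), valid for 1 <= i <= nres-1

    Entries outside the valid index range are NaN (index 0 is never used).
    """

    nres: int
    theta: np.ndarray
    gamma: np.ndarray
    bond_length: np.ndarray

    def theta_window(self, k: int, n: int) -> tuple[float, float, np.ndarray]:
        """Terminal and inner theta of the (k, n) window (n dihedrals,
        n + 3 atoms k..k+n+2): returns (theta_{k+1}, theta_{k+n+1},
        [theta_{k+2}..theta_{k+n}])."""
        self._check_window(k, n)
        return (
            float(self.theta[k + 1]),
            float(self.theta[k + n + 1]),
            self.theta[k + 2 : k + n + 1].copy(),
        )

    def gamma_window(self, k: int, n: int) -> np.ndarray:
        """The n dihedrals gamma_{k+1}..gamma_{k+n} of the (k, n) window."""
        self._check_window(k, n)
        return self.gamma[k + 1 : k + n + 1].copy()

    def _check_window(self, k: int, n: int) -> None:
        if n < 2:
            raise ValueError(f"window needs n >= 2 dihedrals, got n={n}")
        if k < 1 or k + n + 2 > self.nres:
            raise IndexError(
                f"window (k={k}, n={n}) outside chain of {self.nres} residues"
            )


def _pad(values: np.ndarray, first_index: int, nres: int) -> np.ndarray:
    out = np.full(nres + 1, np.nan)
    out[first_index : first_index + len(values)] = values
    return out


def compute_geometry(coords) -> VirtualGeometry:
    """Compute (theta, gamma, bond lengths) from ordered C-alpha coordinates.

    theta_i is the angle at vertex i formed by atoms i-1, i, i+1, in
    (0, 180].  gamma_i is the torsion of atoms i-1, i, i+1, i+2 about the
    i -> i+1 axis, signed by the right-hand rule (IUPAC convention:
    clockwise positive looking from atom i to i+1), wrapped to (-180, 180].
    A collinear triple makes the adjacent dihedral undefined; such entries
    are NaN rather than silently zero.

    Raises DegenerateGeometryError for coincident consecutive points.
    """
    r = np.asarray(coords, dtype=float)
    if r.ndim != 2 or r.shape[1] != 3 or len(r) < 3:
        raise ValueError("need an (N, 3) array with N >= 3")
    nres = len(r)
    b = r[1:] - r[:-1]                       # b[i-1] = bond i (1-based)
    blen = np.linalg.norm(b, axis=1)
    if np.any(blen < 1e-9):
        i = int(np.argmin(blen)) + 1
        raise DegenerateGeometryError(
            f"coincident consecutive points at atoms {i}, {i + 1}"
        )
    u = b / blen[:, None]

    # theta_i = angle(r_{i-1}, r_i, r_{i+1}) = 180 - angle between u_{i-1}, u_i
    cosang = np.einsum("ij,ij->i", u[:-1], u[1:])
    theta = 180.0 - np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))

    gamma = np.full(max(nres - 3, 0), np.nan)
    if nres >= 4:
        b1, b2, b3 = b[:-2], b[1:-1], b[2:]
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        m = np.cross(n1, b2 / np.linalg.norm(b2, axis=1)[:, None])
        x = np.einsum("ij,ij->i", n1, n2)
        y = np.einsum("ij,ij->i", m, n2)
        g = np.degrees(np.arctan2(y, x))
        bad = (np.linalg.norm(n1, axis=1) < 1e-9) | (
            np.linalg.norm(n2, axis=1) < 1e-9
        )
        g[bad] = np.nan
        gamma = wrap_deg(g)
        gamma[bad] = np.nan

    return VirtualGeometry(
        nres=nres,
        theta=_pad(theta, 2, nres),
        gamma=_pad(gamma, 2, nres),
        bond_length=_pad(blen, 1, nres),
    )


def gamma_sum(geom: VirtualGeometry, k: int, n: int) -> float:
    """Wrapped sum Gamma of the n dihedrals gamma_{k+1}..gamma_{k+n}."""
    g = geom.gamma_window(k, n)
    if np.any(np.isnan(g)):
        raise ValueError(f"window (k={k}, n={n}) contains undefined dihedrals")
    return float(wrap_deg(np.sum(g)))


def rebuild_chain(bond_lengths, theta, gamma) -> np.ndarray:
    """Rebuild C-alpha coordinates from internal coordinates (inverse of
    compute_geometry), by sequential natural-extension placement.

    bond_lengths has nres-1 entries (bonds 1..nres-1), theta nres-2 entries
    (theta_2..theta_{nres-1}) and gamma nres-3 entries (gamma_2..gamma_{nres-2}).
    theta values must lie strictly inside (0, 180); the first three atoms are
    placed in a canonical frame (atom 1 at the origin, atom 2 on +x, atom 3
    in the upper xy half-plane).
    """
    d = np.asarray(bond_lengths, dtype=float)
    th = np.asarray(theta, dtype=float)
    ga = np.asarray(gamma, dtype=float)
    nres = len(d) + 1
    if len(th) != nres - 2 or len(ga) != max(nres - 3, 0):
        raise ValueError("inconsistent array lengths for bond_lengths/theta/gamma")
    if np.any(d <= 0):
        raise ValueError("bond lengths must be positive")
    if np.any(th <= 0) or np.any(th >= 180):
        raise DegenerateGeometryError("theta must lie strictly in (0, 180)")

    r = np.zeros((nres, 3))
    r[1] = [d[0], 0.0, 0.0]
    a2 = np.radians(180.0 - th[0])
    r[2] = r[1] + d[1] * np.array([np.cos(a2), np.sin(a2), 0.0])
    for i in range(3, nres):
        a, bpt, c = r[i - 3], r[i - 2], r[i - 1]
        ang = np.radians(th[i - 2])          # theta at vertex i-1 (1-based)
        tor = np.radians(ga[i - 3])          # gamma_{i-2} (1-based)
        blen = d[i - 1]
        local = blen * np.array(
            [-np.cos(ang), np.sin(ang) * np.cos(tor), -np.sin(ang) * np.sin(tor)]
        )
        bc = c - bpt
        bc /= np.linalg.norm(bc)
        ab = bpt - a
        nvec = np.cross(ab, bc)
        nvec /= np.linalg.norm(nvec)
        mvec = np.cross(nvec, bc)
        frame = np.stack([bc, mvec, nvec], axis=1)
        r[i] = c + frame @ local
    return r


def _torsion_of_vectors(b1, b2, b3) -> float:
    """Signed torsion (degrees) of three consecutive direction vectors,
    same convention as compute_geometry's gamma."""
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-12 or np.linalg.norm(n2) < 1e-12:
        raise DegenerateGeometryError("torsion undefined for parallel vectors")
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    return float(wrap_deg(np.degrees(np.arctan2(np.dot(m, n2), np.dot(n1, n2)))))


def axis_dihedral(coords, k: int, m: int) -> float:
    """Dihedral Gamma' formed by the two flanking virtual bonds and the
    least-squares axis of the segment interior.

    The window spans the m atoms k..k+m-1 (1-based); a line is fitted
    through the inner atoms k+1..k+m-2 (principal direction, oriented along
    the chain) and the torsion of (bond k->k+1, axis, bond k+m-2 -> k+m-1)
    is returned.  For near-extended interiors Gamma' approximates the
    wrapped sum Gamma of the window's dihedrals.
    """
    r = np.asarray(coords, dtype=float)
    if m < 5:
        raise ValueError("axis_dihedral needs a window of at least 5 atoms")
    if k < 1 or k + m - 1 > len(r):
        raise IndexError(f"window (k={k}, m={m}) outside chain of {len(r)} atoms")
    w = r[k - 1 : k + m - 1]                 # m atoms, 0-based slice
    inner = w[1:-1]
    centered = inner - inner.mean(axis=0)
    if np.linalg.norm(centered) < 1e-9:
        raise DegenerateGeometryError("inner atoms coincide; no axis defined")
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    if np.dot(axis, inner[-1] - inner[0]) < 0:
        axis = -axis
    return _torsion_of_vectors(w[1] - w[0], axis, w[-1] - w[-2])
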