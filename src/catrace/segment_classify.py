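"""Classification of chain-segment windows by virtual-bond geometry.

A window of n consecutive dihedrals spans m = n + 3 C-alpha atoms starting
at atom k (1-based): terminal virtual-bond angles theta_{k+1} and
theta_{k+n+1}, inner angles theta_{k+2}..theta_{k+n}, and dihedrals
gamma_{k+1}..gamma_{k+n} (the first and last of which are the terminal
dihedrals gamma_N and gamma_C).

Window kinds:

ETB   extended turn-bordered: terminal theta < 100 deg (turns) and every
      inner theta > theta_ext (120 or 135 deg) -- typically a beta strand
      flanked by turns.
NETB  nonextended turn-bordered: terminal theta < 100 deg, inner theta
      <= 120 deg, and no residue of the window interior helix-annotated.
FD    folded: every inner theta < 100 deg, terminals unconstrained.
FH    folded helical: FD and additionally every dihedral in [0, 70] deg or
      the interior residues all helix-annotated.
NS    nonstructured: no residue of the window carries a helix or sheet
      annotation (independent of geometry).

Inequalities are strict/non-strict exactly as listed; windows crossing a
cis- or break-flagged bond are skipped, and all qualifying (k, n) windows
are counted, including overlapping ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .virtual_geometry import VirtualGeometry, gamma_sum

__all__ = [
    "ClassifyParams",
    "Segment",
    "is_etb",
    "is_netb",
    "is_fd",
    "is_fh",
    "is_ns",
    "scan",
    "strip_gly_pro",
    "count_table",
    "KINDS",
]

KINDS = ("ETB", "NETB", "FD", "FH", "NS")


@dataclass
class ClassifyParams:
    theta_turn: float = 100.0
    theta_ext: float = 120.0       # 120 or 135
    theta_fold: float = 100.0
    netb_theta_max: float = 120.0  # fixed regardless of theta_ext
    fh_gamma_lo: float = 0.0
    fh_gamma_hi: float = 70.0
    use_ss_records: bool = True

    def __post_init__(self):
        if not (0 < self.theta_turn <= self.theta_ext < 180):
            raise ValueError("require 0 < theta_turn <= theta_ext < 180")
        if self.fh_gamma_lo >= self.fh_gamma_hi:
            raise ValueError("require fh_gamma_lo < fh_gamma_hi")


@dataclass
class Segment:
    """One classified (k, n) window with its terminal angles and wrapped
    dihedral sum Gamma."""

    chain_id: str
    k: int
    n: int
    kind: str
    gamma_N: float
    gamma_C: float
    theta_N: float
    theta_C: float
    Gamma: float
    contains_gly_pro: bool = False


def _window(geom: VirtualGeometry, k: int, n: int):
    tf, tl, ti = geom.theta_window(k, n)
    return tf, tl, ti


def _helix_free(chain, k: int, n: int) -> bool:
    """True if residues k+1..k+n+1 (window interior, 1-based atoms) carry
    no helix annotation."""
    return not chain.helix_flag[k : k + n + 1].any()


def _all_helix(chain, k: int, n: int) -> bool:
    return chain.helix_flag[k : k + n + 1].all()


def is_etb(geom, k: int, n: int, params: ClassifyParams) -> bool:
    tf, tl, ti = _window(geom, k, n)
    return tf < params.theta_turn and tl < params.theta_turn and bool(
        np.all(ti > params.theta_ext)
    )


def is_netb(geom, chain, k: int, n: int, params: ClassifyParams) -> bool:
    tf, tl, ti = _window(geom, k, n)
    return (
        tf < params.theta_turn
        and tl < params.theta_turn
        and bool(np.all(ti <= params.netb_theta_max))
        and _helix_free(chain, k, n)
    )


def is_fd(geom, k: int, n: int, params: ClassifyParams) -> bool:
    _, _, ti = _window(geom, k, n)
    return bool(np.all(ti < params.theta_fold))


def is_fh(geom, chain, k: int, n: int, params: ClassifyParams) -> bool:
    if not is_fd(geom, k, n, params):
        return False
    g = geom.gamma_window(k, n)
    in_band = bool(
        np.all((g >= params.fh_gamma_lo) & (g <= params.fh_gamma_hi))
    )
    return in_band or _all_helix(chain, k, n)


def is_ns(chain, k: int, n: int) -> bool:
    """No residue of the full window (atoms k..k+n+2) helix/sheet flagged."""
    sl = slice(k - 1, k + n + 2)
    return not (chain.helix_flag[sl].any() or chain.sheet_flag[sl].any())


def _window_ok(chain, geom, k: int, n: int) -> bool:
    """Window lies inside the chain, crosses no flagged bond, and has all
    its angles defined."""
    if k < 1 or k + n + 2 > geom.nres:
        return False
    if chain is not None and chain.flagged_bonds()[k - 1 : k + n + 1].any():
        return False
    tf, tl, ti = geom.theta_window(k, n)
    g = geom.gamma_window(k, n)
    return not (
        np.isnan(tf) or np.isnan(tl) or np.any(np.isnan(ti)) or np.any(np.isnan(g))
    )


def _predicate(kind: str, geom, chain, k, n, params) -> bool:
    if kind == "ETB":
        return is_etb(geom, k, n, params)
    if kind == "NETB":
        return is_netb(geom, chain, k, n, params)
    if kind == "FD":
        return is_fd(geom, k, n, params)
    if kind == "FH":
        return is_fh(geom, chain, k, n, params)
    if kind == "NS":
        return is_ns(chain, k, n)
    raise ValueError(f"unknown segment kind {kind!r}")


def scan(chain, geom: VirtualGeometry, kind: str, n: int,
         params: ClassifyParams | None = None) -> list[Segment]:
    """All (k, n) windows of the chain satisfying the kind's predicate.

    Overlapping qualifying windows are all reported.  Windows containing a
    cis/break bond or an undefined angle are skipped.
    """
    params = params or ClassifyParams()
    out = []
    gp = {"GLY", "PRO"}
    for k in range(1, geom.nres - n - 1):
        if not _window_ok(chain, geom, k, n):
            continue
        if not _predicate(kind, geom, chain, k, n, params):
            continue
        tf, tl, ti = geom.theta_window(k, n)
        g = geom.gamma_window(k, n)
        names = chain.residue_names[k - 1 : k + n + 2]
        out.append(
            Segment(
                chain_id=chain.chain_id,
                k=k,
                n=n,
                kind=kind,
                gamma_N=float(g[0]),
                gamma_C=float(g[-1]),
                theta_N=tf,
                theta_C=tl,
                Gamma=gamma_sum(geom, k, n),
                contains_gly_pro=any(r in gp for r in names),
            )
        )
    return out


def strip_gly_pro(segments) -> list[Segment]:
    """Remove segments whose window contains a glycine or proline residue
    (sequence-reduced data set).  Idempotent."""
    return [s for s in segments if not s.contains_gly_pro]


_TB_NS = list(range(2, 8))                      # ETB/NETB rows: n = 2..7
_FOLD_BINS = ("2", "[3,20]", ">20")             # FD/FH/NS length bins


def _fold_bin(n: int) -> str:
    if n == 2:
        return "2"
    return "[3,20]" if n <= 20 else ">20"


def count_table(dataset, params: ClassifyParams | None = None,
                geoms=None) -> pd.DataFrame:
    """Segment counts by kind and length bin over a set of chains.

    Rows: (ETB, NETB) x n in 2..7 and (FD, FH, NS) x n in {2, [3,20], >20};
    columns: 'all' and 'gly_pro_excluded'.  ``dataset`` is a list of
    annotated CAlphaChain; geometries are computed unless supplied.
    """
    from .virtual_geometry import compute_geometry

    params = params or ClassifyParams()
    rows = [("ETB", str(n)) for n in _TB_NS] + [("NETB", str(n)) for n in _TB_NS]
    rows += [(kind, b) for kind in ("FD", "FH", "NS") for b in _FOLD_BINS]
    counts = {r: [0, 0] for r in rows}

    if geoms is None:
        geoms = [compute_geometry(ch.coords) if ch.nres >= 3 else None
                 for ch in dataset]
    for ch, geom in zip(dataset, geoms):
        if geom is None or ch.nres < 5:
            continue
        for kind in ("ETB", "NETB"):
            for n in _TB_NS:
                segs = scan(ch, geom, kind, n, params)
                counts[(kind, str(n))][0] += len(segs)
                counts[(kind, str(n))][1] += len(strip_gly_pro(segs))
        for kind in ("FD", "FH", "NS"):
            for n in range(2, ch.nres - 2):
                segs = scan(ch, geom, kind, n, params)
                b = _fold_bin(n)
                counts[(kind, b)][0] += len(segs)
                counts[(kind, b)][1] += len(strip_gly_pro(segs))

    index = pd.MultiIndex.from_tuples(rows, names=["kind", "n"])
    return pd.DataFrame(
        [counts[r] for r in rows], index=index,
        columns=["all", "gly_pro_excluded"],
    )


def segments_to_frame(segments) -> pd.DataFrame:
    """Tabular view of a segment list (one row per window)."""
    return pd.DataFrame(
        [
            dict(chain=s.chain_id, k=s.k, n=s.n, kind=s.kind,
                 gamma_N=s.gamma_N, gamma_C=s.gamma_C,
                 theta_N=s.theta_N, theta_C=s.theta_C, Gamma=s.Gamma,
                 gly_pro=s.contains_gly_pro)
            for s in segments
        ],
        columns=["chain", "k", "n", "kind", "gamma_N", "gamma_C",
                 "theta_N", "theta_C", "Gamma", "gly_pro"],
    )
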