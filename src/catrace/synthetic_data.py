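"""Synthetic chains, fixture corpora and Boltzmann dihedral ensembles.

Generators build C-alpha traces in the geometric regimes the classifiers
target (helix: theta ~ 90 deg, gamma ~ 50 deg; turn-bordered extended
segments: large inner theta between two small turn angles; random coil),
with the trans virtual-bond length of 3.8 A.  A single-site Metropolis
sampler draws dihedral vectors from exp(-U/rt) at frozen theta, which
isolates the gamma-coupling mechanism of the multitorsional terms; for
two dihedrals an exact grid oracle provides the reference density.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .mtor_potentials import MtorParams, WindowAngles, dominant_weight
from .structure_io import CAlphaChain, annotate_bonds, write_fixture
from .virtual_geometry import rebuild_chain

__all__ = [
    "EnsembleSpec",
    "make_helix",
    "make_hairpin",
    "hairpin_design",
    "make_coil",
    "make_u_ext_energy",
    "make_u_fold_energy",
    "add_pinning",
    "extended_ensemble_energy",
    "folded_ensemble_energy",
    "sample_gamma_ensemble",
    "grid_oracle",
    "GridDensity",
    "make_fixture_set",
    "BOND_LENGTH",
]

BOND_LENGTH = 3.8


def _chain_from_internal(theta, gamma, chain_id="A", names=None,
                         helix=False, sheet=None) -> CAlphaChain:
    nres = len(theta) + 2
    coords = rebuild_chain([BOND_LENGTH] * (nres - 1), theta, gamma)
    ch = CAlphaChain(
        chain_id=chain_id,
        residue_numbers=np.arange(1, nres + 1),
        residue_names=names or ["ALA"] * nres,
        coords=coords,
    )
    if helix:
        ch.helix_flag[:] = True
    if sheet is not None:
        ch.sheet_flag[sheet] = True
    return annotate_bonds(ch)


def make_helix(nres: int, theta0: float = 90.0, gamma0: float = 50.0,
               flag_records: bool = False, chain_id: str = "A") -> CAlphaChain:
    """Ideal helix: constant theta0/gamma0, optionally helix-annotated.
    The defaults put every interior window in the FD and FH regimes."""
    if nres < 4:
        raise ValueError("need nres >= 4")
    return _chain_from_internal(
        [theta0] * (nres - 2), [gamma0] * (nres - 3),
        chain_id=chain_id, helix=flag_records,
    )


def make_hairpin(len_strand: int = 1, theta_ext_val: float = 150.0,
                 theta_turn_val: float = 90.0, gammas=None,
                 flag_records: bool = False, chain_id: str = "A") -> CAlphaChain:
    """Turn-bordered extended segment with extended flanks.

    The theta profile is [ext, ext, turn, ext*len_strand, turn, ext, ext],
    so exactly one ETB window exists per dihedral count, at start atom
    k = 3 with n = len_strand + 1 dihedrals (the two turn vertices are its
    terminals).  nres = len_strand + 9.  When flag_records is set the
    extended interior residues are sheet-annotated.
    """
    if len_strand < 1:
        raise ValueError("len_strand must be >= 1")
    theta = ([theta_ext_val] * 2 + [theta_turn_val]
             + [theta_ext_val] * len_strand
             + [theta_turn_val] + [theta_ext_val] * 2)
    nres = len(theta) + 2
    if gammas is None:
        gammas = [170.0] * (nres - 3)
    sheet = slice(4, 4 + len_strand + 1) if flag_records else None
    return _chain_from_internal(theta, gammas, chain_id=chain_id, sheet=sheet)


def hairpin_design(len_strand: int) -> tuple[int, int]:
    """(k, n) of the single designed ETB window of make_hairpin."""
    return 3, len_strand + 1


def make_coil(nres: int, seed: int, chain_id: str = "A") -> CAlphaChain:
    """Random coil: theta ~ U(60, 170), gamma ~ U(-180, 180]."""
    if nres < 4:
        raise ValueError("need nres >= 4")
    rng = np.random.default_rng(seed)
    theta = rng.uniform(60.0, 170.0, nres - 2)
    gamma = 180.0 - rng.uniform(0.0, 360.0, nres - 3)
    return _chain_from_internal(theta, gamma, chain_id=chain_id)


# ---------------------------------------------------------------------------
# Boltzmann ensembles of dihedrals at frozen theta

def make_u_ext_energy(theta_profile, params: MtorParams | None = None):
    """Fast closure U(gamma) for the extended term on one window with the
    given theta profile [theta_first, inner..., theta_last]."""
    params = params or MtorParams(a=[3.0])
    tp = np.asarray(theta_profile, float)
    w = dominant_weight(WindowAngles(tp[0], tp[-1], tp[1:-1],
                                     np.zeros(len(tp) - 1)))
    a = np.asarray(params.a, float)
    phi = 0.0 if params.phi is None else float(np.sum(params.phi))

    def energy(gamma) -> float:
        gw = math.radians(float(np.sum(gamma)) + phi)
        return w * sum(a[m] * math.cos((m + 1) * gw) for m in range(len(a)))

    energy.n = len(tp) - 1
    return energy


def make_u_fold_energy(theta_inner, params: MtorParams | None = None):
    """Fast closure U(gamma) for the folded term with the given inner
    theta values (n - 1 of them for n dihedrals)."""
    params = params or MtorParams(b=[3.0])
    ti = np.radians(np.asarray(theta_inner, float))
    gate = float(np.prod(np.sin(ti) ** 2))
    b = np.asarray(params.b, float)
    n = len(ti) + 1
    psi = np.zeros(n) if params.psi is None else np.asarray(params.psi, float)[:n]

    def energy(gamma) -> float:
        g = np.radians(np.asarray(gamma, float) + psi)
        total = 0.0
        for m in range(len(b)):
            total += b[m] * float(np.prod(np.cos((m + 1) * g)))
        return gate * total

    energy.n = n
    return energy


def add_pinning(energy, mu, c: float = 0.75):
    """Add a weak single-dihedral localizing term c * sum_i (1 - cos(g_i -
    mu_i)) to an energy closure.

    Real backbones always carry ordinary single-torsional potentials on
    top of the multitorsional coupling; without them the gamma marginals
    of the pure coupling terms are uniform (the sum- or product-coupled
    density is invariant under shifts/reflections that average each single
    angle out), so circular means -- and with them the scalar circular
    covariance -- are undefined.  The pinning term restores well-defined
    marginals without touching the coupling mechanism under study.
    """
    mu = np.atleast_1d(np.asarray(mu, float))

    def pinned(gamma) -> float:
        g = np.radians(np.asarray(gamma, float) - mu)
        return float(energy(gamma)) + c * float(np.sum(1.0 - np.cos(g)))

    pinned.n = getattr(energy, "n", len(mu))
    return pinned


def extended_ensemble_energy(n: int = 2, a1: float = 3.0,
                             mu=(20.0, -110.0), pin: float = 0.75):
    """Extended-term study energy: u_ext on a (90, 180, ..., 180, 90) theta
    window with the phase sum chosen so the sum-term minimum coincides with
    the pinning centers (defaults: the main terminal-dihedral distribution
    center of turn-bordered extended segments, gamma_N ~ 20, gamma_C ~
    -110), plus weak pinning."""
    mu = np.atleast_1d(np.asarray(mu, float))
    if len(mu) != n:
        raise ValueError("need one pinning center per dihedral")
    # minimum of a1*cos(Gamma_w) is at Gamma_w = 180: set sum of phases so
    # that gamma = mu sits exactly there
    phi_total = 180.0 - float(np.sum(mu))
    params = MtorParams(a=[a1], phi=np.r_[phi_total, np.zeros(n - 1)])
    theta = [90.0] + [180.0] * (n - 1) + [90.0]
    return add_pinning(make_u_ext_energy(theta, params), mu, pin)


def folded_ensemble_energy(n: int = 2, b1: float = -3.0, mu: float = 50.0,
                           pin: float = 0.75):
    """Folded-term study energy: u_fold with phases putting the product
    minimum at the helical dihedral (gamma ~ 50 deg) plus weak pinning that
    selects that mode.  At the minimum every cosine factor is at an
    extremum, so the dihedrals decouple (no cross-correlation)."""
    params = MtorParams(b=[b1], psi=np.full(n, -mu))
    return add_pinning(make_u_fold_energy([90.0] * (n - 1), params),
                       np.full(n, mu), pin)


@dataclass
class EnsembleSpec:
    """Protocol for Metropolis sampling of n dihedrals at frozen theta.

    ``energy`` maps a gamma vector (degrees) to a dimensionless energy;
    rt is the temperature scale (energies are in multiples of RT)."""

    n: int
    energy: object
    rt: float = 1.0
    n_samples: int = 10_000
    burn_in: int = 5_000
    thin: int = 10
    step: float = 30.0
    seed: int = 0

    def __post_init__(self):
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        if not (0.0 < self.step <= 180.0):
            raise ValueError("step must lie in (0, 180]")


def sample_gamma_ensemble(spec: EnsembleSpec) -> np.ndarray:
    """Metropolis chain over n dihedrals: each step perturbs one randomly
    chosen angle by U(-step, step) (wrapped) and accepts with probability
    min(1, exp(-dU/rt)).  Returns (n_samples, n) post-burn-in, thinned
    samples, reproducible by seed."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    gamma = rng.uniform(-180.0, 180.0, n)
    e = float(spec.energy(gamma))
    nsteps = spec.burn_in + spec.n_samples * spec.thin
    idx = rng.integers(0, n, nsteps)
    delta = rng.uniform(-spec.step, spec.step, nsteps)
    accept_u = rng.random(nsteps)
    out = np.empty((spec.n_samples, n))
    j = 0
    energy, rt = spec.energy, spec.rt
    for t in range(nsteps):
        i = idx[t]
        old = gamma[i]
        g = old + delta[t]
        g = 180.0 - (180.0 - g) % 360.0
        gamma[i] = g
        e_new = float(energy(gamma))
        if e_new <= e or accept_u[t] < math.exp(-(e_new - e) / rt):
            e = e_new
        else:
            gamma[i] = old
        if t >= spec.burn_in and (t - spec.burn_in) % spec.thin == spec.thin - 1:
            out[j] = gamma
            j += 1
    return out[:j]


@dataclass
class GridDensity:
    """Exact normalized Boltzmann density on a (gamma_1, gamma_2) grid."""

    centers: np.ndarray          # bin centers, both axes
    cell_prob: np.ndarray        # probability per grid cell (sums to 1)
    resolution: float

    @property
    def density(self) -> np.ndarray:
        """Probability per square degree."""
        return self.cell_prob / self.resolution**2

    def bin_probabilities(self, binwidth: float = 20.0) -> np.ndarray:
        """Aggregate the cell probabilities onto a coarser [-180, 180)
        grid of the given bin width."""
        ncell = len(self.centers)
        per_bin = int(round(binwidth / self.resolution))
        nb = ncell // per_bin
        return (
            self.cell_prob.reshape(nb, per_bin, nb, per_bin).sum(axis=(1, 3))
        )


def grid_oracle(energy, n: int = 2, resolution: float = 1.0,
                rt: float = 1.0) -> GridDensity:
    """Brute-force reference density exp(-U/rt) on a full two-dihedral
    grid over [-180, 180) at the given resolution, sum-normalized."""
    if n != 2:
        raise ValueError("grid_oracle supports n = 2 only")
    centers = np.arange(-180.0 + resolution / 2, 180.0, resolution)
    U = np.empty((len(centers), len(centers)))
    for i, g1 in enumerate(centers):
        for k, g2 in enumerate(centers):
            U[i, k] = energy(np.array([g1, g2]))
    P = np.exp(-U / rt)
    P /= P.sum()
    return GridDensity(centers=centers, cell_prob=P, resolution=resolution)


# ---------------------------------------------------------------------------
# Fixture corpus

def make_fixture_set(out_dir, seed: int = 0) -> Path:
    """Write a small labeled PDB corpus exercising every filter and
    classifier branch; returns the manifest path.  Deterministic by seed.

    Contents: an annotated helix (1.8 A), an unannotated helix (NS-rich,
    1.7 A), a sheet-annotated hairpin (1.9 A), a random coil (1.6 A), an
    'ALLO'-keyword hairpin (1.5 A), an NMR entry (1.5 A) and a low-
    resolution entry (2.4 A).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = [
        ("HEL1", make_helix(20, flag_records=True), 1.8, "xray",
         "ALPHA HELIX", "helix_flagged"),
        ("HEL2", make_helix(20, flag_records=False), 1.7, "xray",
         "DE NOVO PROTEIN", "helix_unflagged"),
        ("HPN1", make_hairpin(1, flag_records=True), 1.9, "xray",
         "BETA HAIRPIN", "hairpin"),
        ("COIL", make_coil(30, seed=seed), 1.6, "xray",
         "DISORDERED PROTEIN", "coil"),
        ("ALLO", make_hairpin(2, flag_records=True), 1.5, "xray",
         "ALLOSTERIC REGULATION", "allosteric"),
        ("NMR1", make_helix(12, flag_records=True), 1.5, "nmr",
         "SOLUTION STRUCTURE", "nmr"),
        ("LOWR", make_helix(12, flag_records=True), 2.4, "xray",
         "LOW RESOLUTION", "low_resolution"),
    ]
    rows = ["path\tentry_id\tdesigned_class"]
    for entry_id, chain, res, method, kw, label in entries:
        p = out / f"{entry_id.lower()}.pdb"
        write_fixture(chain, dict(entry_id=entry_id, resolution=res,
                                  method=method, keywords=kw), p)
        rows.append(f"{p.name}\t{entry_id}\t{label}")
    manifest = out / "manifest.tsv"
    manifest.write_text("\n".join(rows) + "\n")
    return manifest
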