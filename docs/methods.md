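# Methods

## Model and representation

A chain of `nres` Cα atoms is described by its internal coordinates:
virtual-bond lengths d_i (bond i joins atoms i and i+1; ~3.8 Å when the
peptide group is trans, ~2.9 Å when cis), virtual-bond angles θ_i (vertex
at atom i, defined for i = 2..nres−1) and virtual-bond dihedrals γ_i
(about the i→i+1 bond, defined for i = 2..nres−2).  Indexing is 1-based
throughout and each angle carries the index of its defining atom (θ the
vertex, γ the first atom of its axis).  All public angles are degrees;
dihedrals are wrapped to (−180°, 180°] with the upper end closed
(wrap(−180°) = 180°).  The dihedral sign follows the IUPAC right-hand
convention; because the source of a chain may be either handedness, the
convention is pinned by self-consistency tests (rebuild→recompute round
trip, mirror antisymmetry) rather than by an external reference.

A *window* of n dihedrals spans m = n + 3 atoms starting at atom k: two
terminal angles θ_{k+1}, θ_{k+n+1}, inner angles θ_{k+2}..θ_{k+n}, and
dihedrals γ_{k+1}..γ_{k+n}, whose first and last entries are the terminal
dihedrals γ_N and γ_C and whose wrapped sum is Γ.

Chain rebuilding from internal coordinates uses sequential
natural-extension placement (the first three atoms in a canonical frame,
each further atom from the preceding three, bond angle and torsion).  The
round trip reproduces (θ, γ, d) to better than 1e−6°; θ must lie strictly
inside (0°, 180°) for the local frame to exist.

The axis torsion Γ′ of a window is the torsion of (first bond,
least-squares axis of the inner atoms, last bond), the axis oriented
along the chain.  For near-extended interiors Γ′ ≈ Γ; the agreement is
verified by an oracle scan over randomized segments (worst deviation 3.9°
/ 0.65° / 0.11° / 0.006° for interiors within 5° / 1° / 0.1° / 0.01° of
straight), and those frozen bounds are what the test asserts.  Exactly
straight interiors are excluded: there the individual dihedrals (and
hence Γ) are undefined, while Γ′ still exists.

## Structure input and selection

Structures are parsed with gemmi (PDB and mmCIF).  Per chain, residues
without a Cα atom are dropped; alternate locations resolve to the
highest-occupancy copy, first on ties; residues whose author number does
not increase (insertion-code duplicates) are dropped so the per-chain
numbering is strictly monotone.  Secondary structure comes solely from
the file's own HELIX/SHEET (or struct_conf/struct_sheet_range) records —
no DSSP-style recomputation — so the record-dependent classes (NETB, FH,
NS) are exactly as annotated by the depositor; missing categories simply
leave all flags false.

Selection keeps entries with an explicitly defined resolution ≤ 2.0 Å
(boundary inclusive) that are not NMR structures; a keyword filter
(case-insensitive substring, e.g. "ALLO") and a seeded
uniform-without-replacement subsetter support cohort comparisons.

Only Cα atoms are retained, so cis peptide bonds are detected from the
virtual-bond length: d ≤ 3.4 Å flags a cis bond (trans ≈ 3.8, cis ≈ 2.9).
Bonds outside [2.7, 4.3] Å flag chain breaks (missing residues).  No
segment window may cross a flagged bond; chains are effectively split at
breaks rather than discarded.

## Segment classification

With theta_turn = 100°, theta_fold = 100° and theta_ext ∈ {120°, 135°}:

* ETB: terminal θ < 100° and every inner θ > theta_ext (strict);
* NETB: terminal θ < 100°, every inner θ ≤ 120° (this bound stays 120°
  even when ETB uses 135°), and no interior residue helix-annotated;
* FD: every inner θ < 100°, terminals unconstrained;
* FH: FD and (every dihedral of the window within [0°, 70°], or all
  interior residues helix-annotated).  The dihedral-band test is applied
  to all n dihedrals of the window — the natural reading of an otherwise
  self-inconsistent index range in the verbal definition;
* NS: no residue of the window helix- or sheet-annotated (geometry-free).

All qualifying (k, n) windows are counted, overlapping ones included;
shifting a window breaks the turn-bordered definitions, which is what
makes the classes positionally sharp, but nothing in the counting
deduplicates overlaps.  The count table rows are (ETB, NETB) × n = 2..7
and (FD, FH, NS) × n ∈ {2, [3,20], >20}, with an "all" and a "Gly/Pro
excluded" column (windows containing glycine or proline removed, since
those residues dominate turn/terminus statistics).

## Distributions, PMFs, covariances

Histograms use Δθ = 10° and Δγ = 20°, half-open uniform bins.  Dihedral
grids are binned on [−180°, 180°) for the turn-bordered analyses and on
[0°, 360°) for the folded/nonstructured ones, where the helical maxima
would otherwise be split at the wrap point.  Probabilities are counts /
N_tot.  The PMF over Γ is the dimensionless F_i = −ln(N_i/N_tot) shifted
so the occupied minimum is zero; empty bins are masked, never ±∞ (any
reference or Jacobian correction would only move the offset).  The
per-bin covariance map is c_ij = P_ij − P_i P_j with marginals from the
same grid, so Σ c_ij = 0 identically.  As a compact test statistic the
scalar circular covariance mean(sin(x−m_x) sin(y−m_y)) (m the circular
means) is provided; for Markov-chain samples its standard error is
inflated by an effective sample size n(1−ρ)/(1+ρ) from the lag-1
autocorrelation of the product series.

## Multitorsional potentials

The generic n-dihedral term sums over all 2^(n−1) sign vectors with
weights sin θ at the window ends and (1 ∓ cos θ) inside, the (1 − cos θ)
factor on the +1 branch and a 2^−(n−1) prefactor, so that the all-plus
(sum-of-γ) term carries weight exactly 1 when the terminals are at 90°
and the interior is straight.  Per-sign-vector coefficients C_s and
per-dihedral phases are free parameters (defaults 1 and 0).  Two force-
field style terms follow: the extended term `U_e = sinθ_f sinθ_l Π(1−cos
θ_in)/2 · Σ_M a_M cos(M·Γ_w)` with Γ_w the phase-shifted dihedral sum, and
the folded term `U_f = Π sin²θ_in · Σ_M b_M Π_j cos(M(γ_j+ψ_j))`, whose
sin² gate is not inherited from the cumulant expansion but inserted so the
term acts only near 90° interiors (any unimodal gate peaked at 90° would
serve).  The full-chain energy sums U_e + U_f over every window of
2..n_max dihedrals that crosses no flagged bond; defaults M_max = 1,
a = b = (1), phases 0, n_max = 5.  Energies are dimensionless (multiples
of RT).  Both limit identities — u_generic → U_e form at straight
interiors, and u_generic = Π cos γ_j at all-90° angles via the reduction
cos(x+y) + cos(x−y) = 2 cos x cos y — serve as the module's correctness
oracle, and they pin the reconstruction independent of coefficient
conventions.

## Synthetic data and sampling

Generators build chains by inverse geometry at bond length 3.8 Å: ideal
helices (θ = 90°, γ = 50°, optionally helix-annotated), turn-bordered
extended segments with a θ profile [ext, ext, turn, ext×L, turn, ext,
ext] that contains exactly one ETB window (k = 3, n = L + 1), and random
coils (θ ~ U(60°, 170°), γ ~ U(−180°, 180°]).  A fixture corpus adds
entries that exercise each filter branch (NMR, 2.4 Å, "ALLO" keyword).
These chains emulate geometry and annotation only — not sequence
composition, thermal disorder, or experimental-error structure — so
passing tests demonstrate the correctness of the pipeline's bookkeeping
and mechanics, not field-scale statistics of real proteins.

Dihedral ensembles are drawn by single-site Metropolis sampling at frozen
θ (the θ-dependent weights then act as constants, isolating the γ
coupling and keeping the two-dihedral oracle exact): one randomly chosen
angle per step, uniform proposal of half-width 30°, acceptance
min(1, e^−ΔU/RT), burn-in 5000 steps, thinning 10, RT = 1, all seeds
explicit.  For n = 2 the exact reference is exp(−U/RT) evaluated on a 1°
(or 2°) grid and sum-normalized; sampled bin frequencies are required to
match within 3 multinomial standard errors at the autocorrelation-
adjusted effective sample size.

The pure coupling terms leave the single-angle marginals exactly uniform
(the sum-coupled density is invariant under compensating shifts, the
product-coupled one under reflections), so circular means — and with them
the scalar circular covariance — would be undefined on them.  The study
ensembles therefore add a weak localizing term c Σ(1 − cos(γ_i − μ_i)),
c = 0.75, exactly the role ordinary single-torsional potentials play in a
real backbone.  Centers are chosen consistently with each term's minimum:
(20°, −110°) for the extended ensemble — the main terminal-dihedral
distribution center of turn-bordered extended segments, with the phase of
the sum term set so Σμ sits at its minimum — and 50° (helical) for the
folded ensemble, with b < 0 and phases placing the product minimum there.
At that minimum every cosine factor of the folded term is at an extremum,
so its mixed second derivative vanishes and the dihedrals genuinely
decouple; the extended term's sum constraint instead forces compensating
fluctuations.  This is what the verdicts measure: circular covariance
−0.315 (extended), +0.006 ≈ 0 (folded), ≈ 0 (flat control) at 50k
samples.

## Problem sizes and numerical choices

The shipped analyses run on the synthetic corpus (seven entries, chains
of 12–30 residues) and on ensembles of 5×10⁴–2×10⁵ samples; the
geometry round-trip suite uses 1000 random chains of 5–25 residues, and
the classification oracle 100 random chains.  Tolerances: 1e−6° for
geometry round trips, 1e−10 for the analytic limit identities (machine
precision in the exact limits), 3 adjusted standard errors for all
stochastic assertions.  Degenerate inputs are explicit errors (coincident
atoms, θ = 0 frames, empty PMF input) or masked values (collinear-triple
dihedrals become NaN, empty histogram bins stay masked), never silent
zeros.

## Known limitations

* Secondary-structure classes reflect deposited HELIX/SHEET records only.
* Overlapping windows are all counted; a survey that deduplicated them
  would report smaller totals with the same structure.
* The force-field coefficients a_M, b_M, phases and the coupling-length
  cap n_max are exposed but not parametrized against structural data.
* The cis test is length-based and cannot distinguish a genuine cis bond
  from a severely distorted trans bond at ~3.4 Å.
* The scalar circular covariance requires localized marginals; it is
  reported alongside, not instead of, the per-bin covariance map.
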