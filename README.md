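# catrace

Virtual-bond geometry, chain-segment statistics and multitorsional
potentials of protein Cα traces.

## The scientific problem

When a polypeptide backbone is reduced to its Cα trace, its shape is
described by virtual-bond angles θ (three consecutive Cα atoms; ~90° in
helices, >120° in extended strands) and virtual-bond dihedrals γ (four
consecutive Cα atoms).  Averaging the fine-grained degrees of freedom out
of the local interactions leaves a potential of mean force that couples
*consecutive* dihedrals — a multitorsional term.  Its generic form is a
weighted sum of cosines of ±1 combinations of the (phase-shifted) γ
angles,

    U_n = 2^-(n-1) sin θ_f sin θ_l · Σ_{s∈{±1}^(n-1)} C_s
          · Π_j (1 − s_j cos θ_inner,j) · cos(γ_1 + Σ_j s_j γ_{j+1}),

with two analytic limits that carry the physics:

* **Extended interior** (inner θ → 180°, the terminal θ near 90°: a
  β-strand bordered by turns).  The all-plus term dominates with weight
  exactly 1 and the energy depends on the dihedrals only through their
  wrapped sum Γ:  `U_e = w(θ) Σ_M a_M cos(M·Γ)`.  Concerted compensating
  changes of the γ angles are then free — one end of the segment can be
  reoriented at reduced cost if the other end reciprocates, which makes
  such segments natural relays for allosteric coupling, and shows up
  statistically as *anticorrelation* of the terminal dihedrals.
* **Right-angle interior** (inner θ ≈ 90°: helical).  All sign
  combinations get equal weight and the sum telescopes into a product of
  single-angle cosines, `U_f = Π sin²θ_inner · Σ_M b_M Π_j cos(M(γ_j+ψ_j))`
  — each dihedral is directed independently; the segment rigidifies both
  of its ends but does not correlate them.

The package implements the full chain of evidence for this picture:
reading structures and their HELIX/SHEET annotation, computing (θ, γ)
from Cα coordinates, classifying segment windows as extended turn-bordered
(ETB), nonextended turn-bordered (NETB), folded (FD), folded helical (FH)
or nonstructured (NS), building the binned distributions, dimensionless
PMFs over Γ and per-bin covariance maps, and verifying the coupling
mechanism on Boltzmann-sampled dihedral ensembles against an exact
two-dihedral grid oracle.

## Worked example

Evaluate the multitorsional terms on a single extended window
(θ = 90°, 180°, 90°; γ = 30°, −40°):

```
$ catrace potential --theta 90,180,90 --gamma 30,-40
u_generic = 0.984808
u_ext     = 0.984808
u_fold    = 0.000000
```

With a straight interior the generic form and the extended limit agree
exactly — both equal cos(30° − 40°) = 0.9848 — and the folded term is
gated off by its sin²θ factor (sin 180° = 0).

The analysis drivers run the whole pipeline on a synthetic corpus:

```
$ python analysis/01_build_corpus.py
selection (<= 2.0 A, non-NMR) keeps 5: ['ALLO', 'COIL', 'HEL1', 'HEL2', 'HPN1']
'ALLO' keyword keeps: ['ALLO']
$ python analysis/02_scan_segments.py
theta_ext=120: 1136 windows {'ETB': 8, 'FD': 286, 'FH': 272, 'NETB': 83, 'NS': 487}
theta_ext=135: 1133 windows {'ETB': 5, 'FD': 286, 'FH': 272, 'NETB': 83, 'NS': 487}
ETB counts monotone under theta_ext 120 -> 135: True
$ python analysis/04_ensemble_correlations.py
ext  : circ cov = -0.3151 (anticorrelated); max |bin error| vs oracle = 0.0011
fold : circ cov = +0.0064 (uncorrelated); max |bin error| vs oracle = 0.0029
flat : circ cov = +0.0025 (uncorrelated); max |bin error| vs oracle = 0.0009
```

The last block is the mechanism in miniature: ensembles sampled under the
extended term show a clearly negative circular covariance of the two
terminal dihedrals (the sum constraint forces compensating moves), while
the folded term and a flat control do not, and every sampled density
matches the exact grid oracle bin by bin.

The same machinery is exposed as a CLI (`catrace scan / stats / simulate /
fixtures / potential`) for running on real PDB or mmCIF files, with the
survey's selection defaults (resolution ≤ 2.0 Å, non-NMR, Δθ = 10°,
Δγ = 20°, θ_ext ∈ {120°, 135°}).

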