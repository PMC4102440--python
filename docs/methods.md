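# Methods

This note records the models implemented by `chanvar`, the conventions and
default parameters chosen where the underlying methodology is open, and
what the synthetic-data generators do and do not emulate.

## Elastic network models

A structure is coarse-grained to one node per residue (the Cα position when
atomic input is given; residues without a Cα are dropped with a log line).
Uniform springs of force constant γ connect all node pairs within a cutoff.

- **GNM**: the N×N Kirchhoff matrix Γ, Γ_ij = −γ for contacts, rows summing
  to zero. One zero eigenvalue for a connected network.
- **ANM**: the 3N×3N Hessian with super-elements
  −(γ/d_ij²)·(r_ij ⊗ r_ij); six zero modes for a connected, non-collinear
  structure (five for a collinear one).

Defaults: cutoff 7.0 Å (GNM) and 15.0 Å (ANM), γ = 1 — the conventional
choices in the ENM literature; all exposed as parameters. Eigenvalues are
sorted ascending and modes with λ < 10⁻⁸·λ_max are flagged as rigid-body
modes; more zero modes than expected signals a disconnected or degenerate
structure (a warning, not an error). The arbitrary global sign of each
eigenvector is fixed by making its first significant component positive, so
domain partitions are reproducible across LAPACK builds.

Per-residue square fluctuations from the k slowest nonzero modes are
Σ_k λ_k⁻¹ |v_k(i)|² in units of k_BT/γ (ANM components summed per residue);
summed over all nonzero modes this equals the pseudo-inverse diagonal, which
the tests verify against `numpy.linalg.pinv`. Domain partitions label
residues by the sign of the mode shape (ANM modes are first projected on
their dominant displacement axis); components below `hinge_band` (default
0.1) of the maximum magnitude are hinge residues, as are residues flanking
a sign change. The hinge band is a graphical convention — published hinge
assignments are typically read off mode-shape plots — so the default is a
judgement call, exposed as a parameter.

The dense symmetric eigensolver is used up to 5000 nodes; larger inputs are
rejected with a clear error rather than silently degrading.

## Pore geometry

Two distinct width measures are implemented and deliberately kept apart:

- **Radius profile**: at each elevation along a chosen axis, the radius of
  the maximal disc (probe center optimized in-plane by Nelder–Mead from the
  axis seed, never further than `max_shift`, default 5 Å) whose clearance
  to every atom — 3-D center distance minus that atom's van der Waals
  radius — is maximal. This reads "the largest circle fitting the
  cross-section" as the maximal inscribed disc per slice, the HOLE-style
  convention. Occluded elevations report 0; slabs containing no atoms
  report NaN. The slab half-width is step/2 plus the largest vdW radius in
  the selection so no atom can be missed between slices.
- **Site diameter**: the closest interatomic center-to-center distance
  between two named residues (e.g. a mutation site and the residue across
  the cavity), *not* reduced by vdW radii — matching how per-site channel
  diameters are conventionally reported from MD. Tracked per frame across
  a trajectory.

Constriction statistics (mean, sample SD, histogram with 30 equal-width
bins by default) discard an initial equilibration window; the default is
the first 10% of the simulated span (production MD conventionally discards
an initial segment), configurable in ps. Superposition RMSD uses the
Kabsch SVD solution with an explicit rotation applied, avoiding the
cancellation error of the closed-form expression near zero RMSD.

## Ion geometry

An ion is a union of atom-centered vdW spheres. The minimal bounding box is
searched over a uniform Euler-angle grid (default 5°) followed by
Nelder–Mead refinement; the search is deterministic for a fixed grid, and
finer grids can only shrink the found volume. The box algorithm behind the
published bicarbonate box is not described anywhere, so this is the
package's own choice; the refinement makes the result insensitive to the
grid within ~0.1%.

Two published conventions convert the sorted box extents (e₀ ≤ e₁ ≤ e₂) to
one equivalent radius: `half_second_largest` → e₁/2 and
`mean_two_smallest_halves` → (e₀ + e₁)/4. For the published bicarbonate box
3.40 × 4.86 × 5.39 Å these give 2.43 Å and 2.065 Å; which rule produced the
printed "2.1 Å" is not stated, and the mean-of-two-smaller-halves reading
(which rounds to 2.1) is an inference, flagged as such. Chloride is a
single sphere of radius 1.81 Å. The bundled bicarbonate geometry is a
constructed planar stand-in from textbook bond lengths (its file and
docstring say "synthetic"); it reproduces the 3.40 Å thickness (twice the
carbon vdW radius) but its in-plane extents differ by ~0.2 Å from the
published DFT-derived box.

## Electrophysiology

Ramp traces are (voltage, current) samples over a −100→+100 mV ramp
(nominally 250 ms at 5 kHz), with cell capacitance and a liquid-junction
offset that is subtracted from the command voltage before any analysis.

The reversal potential is the zero-current crossing: located by linear
interpolation on a short moving-average-smoothed copy of the current
(window ≈ 2% of the ramp, suppressing spurious noise crossings), then
refined as the root of a least-squares line fitted to the raw samples
within ±30 mV of the crossing. Both steps are exact for noise-free traces;
the ±30 mV window averages enough samples (~375 at the nominal rate) that
the root error stays below 0.5 mV at 2% current noise. Multiple crossings
are resolved toward 0 mV with a warning.

The printed bi-ionic GHK expression in the source methods text is
typographically garbled (it subtracts a concentration ratio inside an
exponential argument and is not dimensionally coherent), so the standard
bi-ionic relation for monovalent anions is implemented:

    P_X/P_Cl = ([Cl]'_o · exp(−ΔE_rev·F/RT) − [Cl]_o) / [X]_o

with [Cl]'_o the control bath chloride (150 mM: 146 NMDG-Cl + 1 CaCl₂ +
1 MgCl₂), [Cl]_o the residual chloride of the substituted bath (10 mM) and
[X]_o the test anion (140 mM bicarbonate). Two checks pin this form down:
with zero shift it gives (150−10)/140 = 1 (the symmetric-substitution
limit), and a poorly permeant anion produces a *positive* shift
(+31.7 mV at P_X/P_Cl = 0.24), matching the reported direction. RT/F is
computed from the solution temperature; the recording temperature is not
stated, so 298.15 K is the default. The inversion is exact against the
forward GHK map over P ∈ [0.05, 5] (round-trip error < 10⁻⁶).

Chord conductance is the least-squares I–V slope over
[E_rev, E_rev + 25 mV] (window configurable); current density divides
currents by capacitance and marks the result so normalization is
idempotent.

## Cohort association

Carrier (dominant) coding throughout: a subject is exposed if they carry at
least one allele. Genotype classes are assigned with precedence
recessive (≥2 pathogenic alleles including ≥1 BD) > trans-heterozygote
(exactly one SPINK1 N34S allele plus ≥1 panel CF/BD allele; N34S
homozygotes are excluded from trans-het analysis because that genotype is a
sufficient risk factor alone) > single-class carrier > none. Cis-phase
rules: R117H counts as CF only when an explicit phase column marks it in
cis with the intron-8 T5 allele, otherwise it stays BD with a warning;
IVS8-T5 counts as CF only under its own cis rule and otherwise toward no
risk class.

Statistics: odds ratio (a·d)/(b·c) with degenerate tables reported as 0, ∞
or undefined rather than continuity-corrected (matching how sparse
rare-variant tables are published; a Haldane–Anscombe-corrected variant
would be a one-line change). Fisher's exact two-tailed p sums hypergeometric
probabilities not exceeding the observed one (computed via log-gamma with a
10⁻⁹ relative tie slack; an exhaustive integer-arithmetic enumeration
oracle confirms agreement within 10⁻¹⁰ for every table with n ≤ 60).
Pearson chi-square (1 df, Yates off by default) is used when all expected
counts reach 5, Fisher otherwise. Confidence intervals are Woolf (log-OR
normal) intervals; published intervals for the same tables differ slightly
(e.g. 1.19–2.38 vs Woolf 1.20–2.33 for the all-cases sinusitis table),
indicating an unstated interval method in the source; the discrepancy is
documented rather than reverse-engineered.

## Synthetic data

All generators draw from a single `numpy.random.default_rng(seed)`; the
same seed and configuration reproduce identical datasets.

- **Elastic dumbbell**: two globular domains (default 30 nodes each,
  radius 6 Å, minimum spacing 2.8 Å) joined by a thin linker (default 4
  nodes at 3.5 Å spacing, small lateral jitter to avoid exact collinearity).
  A deterministic "pole" node in each domain faces the linker so the chain
  is connected at the 7 Å GNM cutoff; disconnected samples are regenerated
  from a shifted sub-seed with a log line. The linker range is the
  ground-truth hinge; the hinge-in-linker recovery test passes a 20-seed
  sweep.
- **Constriction series**: a discrete Ornstein–Uhlenbeck process with
  stationary mean μ and SD σ. Defaults: frame interval 10 ps, relaxation
  time 2.5 ps, i.e. successive saved frames are nearly decorrelated —
  emulating sparsely saved MD frames and making the sample mean's error
  behave like that of n independent draws (the recovery tolerance
  3σ/√n assumes this). σ > μ/2 is rejected as non-physical. The reported
  MD moments (10.3→7.5 Å with σ 0.5; 9.9→4.3 Å with σ 1.1) are used as
  generator parameters, not as recomputable results.
- **Walled pore**: atom rings stacked along z whose center-line radius is
  constriction_radius + vdW at the constriction and widens quadratically,
  so the inscribed-disc radius at the constriction equals the planted value
  exactly.
- **Ramp pairs**: reversal potentials set by the chloride gradient (10 mM
  pipette / 150 mM bath) and the GHK forward map at the planted P_X/P_Cl;
  currents linear in voltage (whole-cell CFTR-like currents are close to
  ohmic) with planted conductances and additive Gaussian noise scaled to
  max |I|.
- **Cohorts**: exact-count mode plants contingency cells deterministically
  (so printed tables reproduce without sampling noise); binomial mode
  samples heterozygous carriers at given frequencies (homozygosity is
  negligible at rare-variant frequencies), N34S at 5.6% in cases / 2% in
  controls (the control frequency is not published; 2% is a typical
  population value), and phenotype flags from baseline odds (10.2%
  rhinosinusitis) times per-stratum multipliers.

What the generators do **not** emulate: molecular-dynamics physics or force
fields, linkage disequilibrium between variants, genotyping error, or
patch-clamp artifacts beyond additive Gaussian noise. Passing recovery
tests therefore demonstrates correctness of the analysis pipeline under its
stated statistical assumptions, not fidelity of those assumptions to any
particular experimental dataset.

## Problem sizes and numerical choices

The test suite runs at desk scale: ENM structures of 15–64 nodes,
5000-frame constriction series, 1250-sample ramps, cohorts up to 10⁴
subjects, and the exhaustive Fisher sweep over all 635 376 tables with
n ≤ 60. Nelder–Mead tolerances (xatol 10⁻⁹ for pore probes, 10⁻⁶ degrees
for box orientation) keep profile values reproducible under rigid motion to
10⁻⁶ Å. Ties in Fisher enumeration are included via a 10⁻⁹ relative slack;
eigenvector signs, mode indexing (1-based over nonzero modes) and histogram
binning (30 equal-width bins over the observed range) are fixed conventions
stated above.

## Known limitations

- ANM partitions reduce a 3-D mode to one signed scalar by projection on
  the mode's dominant axis; modes with strongly curved displacement fields
  may partition differently than a visual inspection would suggest.
- The pore profile's local search can under-report the radius for strongly
  non-convex slices (multiple pockets), and `max_shift` bounds how far the
  probe may wander off-axis.
- The bounding-box search is grid-seeded; pathological ions with many
  near-degenerate optimal orientations could require a finer grid than the
  5° default.
- Phenotype association treats subjects as independent; no covariate
  adjustment or relatedness correction is provided.
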