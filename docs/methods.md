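# Methods

This note documents the model implemented by `cgdamage`, the choices
made where the design was genuinely open, and what the synthetic study
conditions do and do not establish.

## Coarse-grained geometry

Each nucleotide is represented by three spherical interaction sites:
phosphate, deoxyribose and base. Atoms are assigned by name: the
phosphate cluster is {P, OP1, OP2, O5′}, the deoxyribose cluster is
{C1′–C5′, O4′, O3′}, and everything else belongs to the base. The
bridging oxygens of the phosphodiester linkage are split across the
boundary — O5′ with the phosphate, O3′ with the sugar — so that no atom
is double-counted. From the nucleotide's point of view this split is
energy-neutral: the ~3 eV a cluster loses at one boundary the
neighbouring cluster gains, and a nucleotide is damaged when *either*
backbone bead is broken.

Bead centers are the unweighted centroids of the cluster heavy atoms.
Bead radii derive from the van der Waals union volume of the cluster,
`r = (3V/4π)^(1/3)`. Union volumes can be estimated by Monte Carlo
rejection sampling or voxel counting (both implemented, cross-checked
against the analytic two-sphere union), or supplied directly; the
reference values 0.050, 0.084 and 0.104 nm³ give radii of 2.3, 2.7 and
2.9 Å. We ship Bondi radii (C 1.70, N 1.55, O 1.52, P 1.80 Å); with the
generated template geometry they reproduce the reference volumes to
within ~4 % for phosphate and sugar and ~13 % for the base, so the soft
validation band on volumes is ±15 % — the exact radii set behind the
reference numbers is not recorded, and the base is a generic purine-like
ring system rather than a specific base.

### Atomic fixture models

The original atomic plasmid models are not deposited, so the package
generates parametric heavy-atom B-DNA: canonical rise 3.38 Å and twist
36°/bp, a rigid per-nucleotide template, two antiparallel strands
(the second strand's template is flipped so its backbone runs in the
opposite direction). The phosphate group is embedded from the exact
six-distance matrix of the reference worked example (P–OP1 1.480,
P=OP2 1.482, P–O5′ 1.598, OP1–OP2 2.520, OP1–O5′ 2.506, OP2–O5′
2.463 Å), which anchors the potential calculation; sugar and glycosidic
bonds sit at the equilibrium distances of the parameter table. Circular
models bend the helical axis onto a closed circle (twist rounded to an
integer number of helical turns so the duplex closes); the supercoiled
form uses a figure-eight axis with one crossing, matching the dominant
morphology of negatively stained dried plasmids. Whether the supercoil
pitch of the 1/10-scale (436 bp) plasmid was rescaled in the original
models is unknowable from the record; the figure-eight geometry here is
a free choice and only its writhe (one crossing) is asserted.

## Cluster potentials as damage thresholds

The threshold of a backbone bead is |U_total| of its cluster, with

* Morse wells over covalent bonds, `U₁(r) = D_e[e^(−2α(r−r_e)) −
  2e^(−α(r−r_e))]`, `α = √(k_e/2D_e)`; the force constant k_e is set by
  bond order (5/10/15 × 10⁵ dyn/cm for single/double/triple). α is
  always recomputed from (k_e, D_e) rather than read from a rounded
  table column. Note the sign convention: this standard well form has
  `U₁(r_e) = −D_e` and reproduces every reference bonded energy; a
  variant floating around with a leading `D_e{1 − …}` does not.
* Lennard-Jones 12-6 terms over all remaining atom pairs in the
  cluster, reusing the (r_e, D_e) of the matching element pair and
  `σ = r_e/2^(1/6)`. This convention exactly reproduces the three
  reference O···O energies.
* Angle and torsion terms are omitted (≲10 % of the total for these
  small clusters).

One printed reference value is internally inconsistent: the P–O5′ row
is given as −3.4339 eV, but the printed column total (−12.3562 eV) is
only consistent with −3.4399 eV, which is also what direct evaluation
of the Morse formula gives. We treat the total as authoritative.

The deoxyribose inventory is an assumption: the cluster keeps its seven
internal bonds (four C–C, C1′/C4′–O4′, C3′–O3′) plus the C5′–O5′
boundary bond (configurable via `include_c5_o5_bond`). With the
template geometry this yields 32.8 eV, within 10 % of the 30.5 eV
reference; the exact bond list behind that reference number is not
recorded, so the threshold check is a soft band, not an equality.

Bases carry no threshold: direct damage is modelled as phosphodiester
backbone cleavage only. Base beads still exist in the geometry and can
absorb deposits (keeping energy bookkeeping honest), they just never
break.

## Phantom

Segment copies are wrapped in a cuboid mother volume — the bounding box
of the bead scoring spheres plus a 1 nm margin — and placed uniformly
at random (position and orientation) in a water sphere, rejecting any
placement whose oriented box intersects an existing one
(separating-axis test) or pokes outside the sphere. Form mixing uses
exact largest-remainder counts (90 % supercoiled / 10 % relaxed by
default, the morphology of dried plasmid preparations). The reference
configuration, 5400 × 436 bp in a 3 µm sphere, has a bp density of
2.08 × 10⁻⁵ bp/nm³ — consistent with the experimental value of about
2.1 × 10⁻⁵ bp/nm³ (a published figure of 22.1 × 10⁻⁵ for the same
configuration does not survive the arithmetic; we use the computed
value and keep the density configurable).

## Synthetic tracks and scoring

The built-in event generator is **not** a transport code. Each primary
is a straight chord of the phantom sphere: entry point uniform on the
surface, direction cosine-weighted toward the inside (uniform external
irradiation; mean chord 4R/3). Deposits follow a Poisson process along
the chord with linear density λ = LET / E̅ (E̅ = 40 eV mean deposit
energy by default), exponential energies, and isotropic Gaussian blur
(σ = 2 nm). It reproduces two first-order facts — deposit density
scales with LET, and tracks are sparse at the micrometre scale — and
exists to exercise scoring and classification. Real track-structure
output can be ingested through the TSV event format instead.

Scoring: each deposit goes to the nearest bead center among beads whose
scoring radius contains it (exact ties to the lowest bead index);
energy accumulates per (event, bead) and resets between events, so a
primary either breaks a bead or does not. Scored + unassigned energy
equals deposited energy exactly. The k-d-tree implementation is
contract-tested against the O(N·M) brute force. The scoring radius is
either the bead's own VDWR radius or a fixed 3.4 Å for both backbone
beads — the first ordered water shell around duplex DNA lies within
~3.4 Å, and charge transfer from that shell contributes to direct
damage; hydration mode is the default.

Absorbed dose is total deposited energy over the water sphere mass
(1 MeV in a 3 µm sphere = 1.4167 Gy, the bookkeeping oracle).

## Break classification

A nucleotide breaks in an event when its phosphate *or* deoxyribose
score strictly exceeds the bead threshold. Per event and molecule,
breaks link into proximity clusters (≤ 10 bp apart, modular distance on
circles) and each cluster is reported once at its most complex class,
ordered SSB < SSB⁺ < 2SSB < DSB < DSB⁺ < DSB⁺⁺:

* a mixed-strand cluster always contains an opposite-strand pair within
  10 bp (links are ≤ 10 bp), so it is DSB-class: DSB⁺⁺ when two
  disjoint opposite-strand pairs exist, DSB⁺ when a lone pair has extra
  company, DSB otherwise;
* single-strand clusters are SSB (isolated) or SSB⁺ (≥ 2 breaks);
* SSB-class clusters on opposite strands — automatically > 10 bp apart —
  pair up as 2SSB, most complex lesions first, so the outcome depends
  only on per-strand class counts and is invariant under relabelling
  and circular shifts.

The original clustering flowchart lives in an unavailable supplement;
the taxonomy above is the standard clustered-lesion scheme consistent
with the listed classes and the most-complex-type rule, and is
contract-tested against an exhaustive graph-matching oracle. Two open
choices are ours and configurable: a 2SSB counts as **two** units in
the SSB yield (two separate single-strand lesions; flag
`two_ssb_units`), and the DSB-pair count uses an exact
two-disjoint-pair test rather than greedy pairing, which removes any
order dependence. Yields are (SSB + SSB⁺ + 2·2SSB) and
(DSB + DSB⁺ + DSB⁺⁺) per Gy per Gbp.

## McMahon dose-response fitting

The three plasmid band fractions follow
`SC(D) = S₀e^(−(μ+φ)D)`,
`OC(D) = e^(−φD)[e^(−0.5μ²ρD²)(S₀+C₀) − S₀e^(−μD)]`,
`L(D) = 1 − (S₀+C₀)e^(−(φD+0.5μ²ρD²))`; they sum to one identically.
μ and φ (per plasmid per Gy; divide by n_bp × 10⁻⁹ for Gy⁻¹ Gbp⁻¹) are
fitted to the OC band only — the best-constrained band — by
multi-start nonlinear least squares with S₀, C₀ read from the
zero-dose lane. ρ, the probability that two independent SSBs form a
DSB, is held fixed at (2·10+1)/n_bp ≈ 0.0048 for pBR322 (4361 bp): a
second SSB within ±10 bp on the opposite strand. Doubling or halving
ρ moves the recovered μ by under 1 % and φ by a few % in the synthetic
studies (the ρ-term only matters where μ²ρD² ≳ 1).

The published gel datasets are not tabulated, so the printed yields
(e.g. μ = 57.4 ± 2.25, φ = 3.87 ± 1.21 Gy⁻¹ Gbp⁻¹ for ⁶⁰Co on dried
pBR322) cannot be re-fitted; instead the synthetic generator produces
band fractions from the forward model at those yields with 2 %
Gaussian band noise (clipped and renormalized to sum to one), and the
fitter is validated by recovery: exact (< 10⁻⁴ relative) on noiseless
data, unbiased within 2 SE of the replicate mean over 100 noisy
replicates. The synthetic dose ladder spans 0–8 kGy in 9 lanes — the
range over which all three bands stay quantifiable (SC ≥ ~10 %) at
these yields, as a practical gel design would require; dried-plasmid
assays operate at kGy doses because without radical-mediated chemistry
the per-Gy damage is small.

## Scaled-down study conditions

Two stochastic studies run at deliberately small scale:

* **LET ladder.** 20 plasmid segments (436 bp, 90/10 supercoiled/
  relaxed) in a 0.11 µm sphere — a bp density ~150× the dilute
  experimental value, comparable to the density of the published
  linear-DNA configuration — irradiated at 20/40/80/160/320 keV/µm to
  a target dose of 6 × 10⁵ Gy per rung, five seeds. At this scale the
  SSB/DSB ratio falls monotonically with the clustering surrogate
  (pooled Spearman ρ ≈ −0.95, p ≈ 10⁻¹²), reproducing the qualitative
  high-LET trend. The absolute published SSB/DSB curves and the ~14 %
  agreement with experiment depend on real track-structure physics
  (secondary electron cascades, energy-loss straggling) that the
  Poisson-chord surrogate deliberately does not model; users with real
  MCTS output can replay it through `tracks.read_events` and the same
  scoring/classification stages.
* **Yield recovery.** 30–100 noisy gel replicates as above.

Passing these checks shows the machinery — thresholds, scoring,
clustering, fitting — is internally consistent and reproduces the
model's analytic anchors; it does not by itself validate the surrogate
track model against measured yields.

## Numerical choices

* Units: coordinates in Å inside atomic/CG modules, nm in
  phantom/track modules (converted at the `BeadArray` boundary);
  energies in eV; 1 dyn/cm = 10⁻³ N/m; 1 eV = 1.602 176 634 × 10⁻¹⁹ J.
* Threshold comparison is strict (`>`).
* Nearest-bead ties break to the lowest bead index.
* The CG text format round-trips at 6 decimals; PDB at 3 (PDB-borne
  geometries therefore reproduce cluster energies to ~0.01 eV, not
  10⁻⁴ eV).
* Every stochastic routine takes an explicit seed; pipeline stages
  derive seeds from a master seed via `numpy` SeedSequence spawning.

## Known limitations

* No transport physics, no chemistry stage, no indirect (radical)
  damage — appropriate for dried-plasmid direct-damage conditions only.
* Base damage is not modelled; base beads only absorb energy.
* The B-DNA template is sequence-generic; base identity never enters.
* Geant4-style constructive solid geometry for overlapping beads is
  emulated by nearest-center assignment, which guarantees no double
  counting but draws slightly different boundaries between adjacent
  scoring spheres.
* The 146 bp linear-DNA configuration with millions of segments is
  supported by the same placement machinery but has not been exercised
  at full scale; its published segment count is inconsistent with the
  stated density, so density is always configurable.
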