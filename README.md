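# cgdamage

Coarse-grained (CG) modelling of **direct radiation damage to DNA**, with
experimental yield quantification for plasmid relaxation assays.

Ionizing radiation breaks DNA strands when enough energy is deposited in
the sugar–phosphate backbone. Track-structure simulations score energy
deposits in nanometre-scale volumes around the backbone and declare a
strand break when the per-event cumulative energy in a volume exceeds a
threshold. Historically that threshold has been an empirical fit
parameter (values between 5 and 37.5 eV are in circulation). `cgdamage`
implements a first-principles alternative: each nucleotide is reduced to
three beads (phosphate, deoxyribose, base), and the damage threshold of
a backbone bead is the magnitude of its cluster pair-potential energy,

```
U_total ≈ Σ U_Morse(r) + Σ U_LJ(r)
U_Morse(r) = D_e [e^(−2α(r−r_e)) − 2 e^(−α(r−r_e))],  α = √(k_e / 2 D_e)
U_LJ(r)    = 4 D_e [(σ/r)^12 − (σ/r)^6],              σ = r_e / 2^(1/6)
```

summed over the covalent bonds (Morse) and the remaining non-bonded atom
pairs (Lennard-Jones) of the bead's atomic cluster. With standard bond
parameters this gives **12.4 eV** for the phosphate group (P, OP1, OP2,
O5′) and **≈30.5 eV** for the deoxyribose group — inside the established
empirical range, but derived without fitting to damage data.

The package covers the full workflow:

* **`cgdamage.fixtures`** — parametric heavy-atom B-DNA models (linear,
  relaxed circular, figure-eight supercoiled plasmid) and PDB I/O.
* **`cgdamage.cgbuild`** — moiety partition, van der Waals union
  volumes, bead radii `r = (3V/4π)^(1/3)`, CG geometry text format.
* **`cgdamage.potential`** — Morse/LJ pair energies and cluster
  thresholds from an editable bond-parameter CSV.
* **`cgdamage.phantom`** — non-overlapping random placement of segment
  copies in a spherical water phantom (e.g. 5400 plasmids, 90 %
  supercoiled / 10 % relaxed, in a 3 µm sphere).
* **`cgdamage.tracks`** — a synthetic per-primary energy-deposition
  generator (a documented surrogate for Monte Carlo track-structure
  codes), TSV ingestion of real track output, nearest-bead scoring and
  absorbed-dose bookkeeping.
* **`cgdamage.damage`** — threshold comparison → strand breaks, 10-bp
  clustering into SSB/SSB⁺/2SSB/DSB/DSB⁺/DSB⁺⁺, yields per Gy per Gbp.
* **`cgdamage.mcmahon`** — the McMahon dose-response model for
  supercoiled/open-circular/linear gel band fractions,
  `SC(D) = S₀e^(−(μ+φ)D)` etc., with nonlinear fitting of the SSB yield
  μ and DSB yield φ from the open-circular band.

## Worked example

```python
from cgdamage.fixtures import build_bdna
from cgdamage.cgbuild import partition_nucleotide
from cgdamage.potential import cluster_potential, load_bond_params

model = build_bdna(10, "linear", "straight")
_, nucleotide = next(iter(model.nucleotides()))
part = partition_nucleotide(nucleotide)
params = load_bond_params()

phosphate = cluster_potential(part.phosphate_atoms, params)
for p in phosphate.pair_energies:
    print(f"{p.atom_a:>4}-{p.atom_b:<4} {p.kind:<10} r={p.distance:.3f} A  "
          f"U={p.energy:+.4f} eV")
print(f"U_total = {phosphate.u_total:.4f} eV -> threshold "
      f"{phosphate.threshold:.1f} eV")
```

prints

```
 O5'-P    bonded     r=1.598 A  U=-3.4399 eV
   P-OP1  bonded     r=1.480 A  U=-2.9038 eV
   P-OP2  bonded     r=1.482 A  U=-5.6294 eV
 O5'-OP1  nonbonded  r=2.506 A  U=-0.1246 eV
 O5'-OP2  nonbonded  r=2.463 A  U=-0.1379 eV
 OP1-OP2  nonbonded  r=2.520 A  U=-0.1206 eV
U_total = -12.3562 eV -> threshold 12.4 eV
```

i.e. three Morse wells for the covalent P–O bonds, three small LJ terms
for the O···O contacts, and a 12.4 eV break threshold for the phosphate
bead. An end-to-end run (geometry → phantom → synthetic tracks → break
classification) is one command:

```sh
cgdamage run -c config.yaml -o run/
```

which writes per-LET SSB and DSB yields (Gy⁻¹ Gbp⁻¹) and their ratio to
`run/summary.csv`. The individual stages are also exposed
(`cgdamage fixtures build`, `cgdamage cg build`, `cgdamage phantom`,
`cgdamage tracks simulate|score`, `cgdamage damage classify`,
`cgdamage gel simulate|fit`).

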