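# coedecomp

Decomposition of intrinsically disordered protein (IDP) conformational
ensembles into radius-of-gyration (Rg) groups, with per-group structural
characterization.

IDPs do not fold into a single structure; in solution they populate a broad
conformational ensemble, and low-resolution solution scattering sees only
its average. This package implements the complementary, simulation-side
analysis: sort an ensemble's frames by the mass-weighted radius of gyration

    Rg = sqrt( Σᵢ mᵢ ‖rᵢ − r_com‖² / Σᵢ mᵢ ),

bin them into integer-Å groups, and compute for each group the observables
that reveal what conformer classes the average hides:

- **Scattering** — Debye-formula profiles I(q) = ΣᵢΣⱼ fᵢ(q)fⱼ(q) sinc(q rᵢⱼ)
  from Cromer–Mann vacuum form factors, Kratky transforms q²I(q), direct
  pair-distance distributions P(r) with r_max, and reduced
  χ² = (1/N)Σ((Eᵢ−cSᵢ)/σᵢ)² against an experimental curve.
- **Surfaces and contacts** — Shrake–Rupley solvent-accessible surface area
  per residue (raw and normalized against theoretical maximum-ASA
  baselines), geometric hydrogen-bond occupancy maps, residue–residue
  contact maps, and the (Rg, total SASA) kernel density.
- **Flexibility and landscapes** — per-residue RMSF about iteratively
  converged group mean structures, GROMOS (Daura) RMSD clustering, tICA via
  the symmetrized generalized eigenproblem C_τv = λ(C₀+εI)v, and
  −ln(density) free-energy landscapes in kT over the two leading components.
- **Secondary structure** — φ/ψ tables, Ramachandran histograms and region
  integration (β, PPII, α, left-handed helix windows), and a reduced DSSP
  (helix / strand / H-bonded turn / PPII / coil) built on Kabsch–Sander
  H-bond energies.

All operators are implemented natively (numpy/scipy only) and
cross-checked in the test suite against closed forms, brute-force oracles
and, where available, independent implementations. Because multi-
microsecond MD input is impractical to ship, a **synthetic ensemble
generator** produces histatin-5-like backbone ensembles with exact,
controllable Ramachandran-region occupancies, a broad smooth Rg
distribution, and optional two-state Markov switching between compact and
extended dihedral regimes — ground truth for every downstream stage.

See `docs/methods.md` for the models, conventions and defaults in detail.

## Worked example

```python
import numpy as np
from coedecomp import (GeneratorConfig, generate_ensemble, assign_rg_groups,
                       group_histogram, pair_distance_distribution,
                       region_fractions, backbone_dihedrals)

ens = generate_ensemble(GeneratorConfig(n_frames=500, seed=1))
groups = assign_rg_groups(ens)
print("Rg groups (label: count, fraction):")
for lab, (count, frac) in group_histogram(groups).items():
    print(f"  {lab:2d} A: {count:4d}  {frac:.3f}")
print(f"mean Rg = {groups.rg_per_frame.mean():.2f} A")

for lab in (groups.labels[0], groups.labels[-1]):
    pr = pair_distance_distribution(ens, groups.members[lab])
    print(f"group {lab:2d} A: r_max = {pr.r_max:.1f} A")

fracs = region_fractions(backbone_dihedrals(ens))
print("Ramachandran region fractions:",
      {k: round(v, 3) for k, v in fracs.items()})
```

prints

```
Rg groups (label: count, fraction):
   7 A:    3  0.006
   8 A:   17  0.034
   9 A:   40  0.080
  10 A:   63  0.126
  11 A:   86  0.172
  12 A:   73  0.146
  13 A:   79  0.158
  14 A:   57  0.114
  15 A:   38  0.076
  16 A:   28  0.056
  17 A:   10  0.020
  18 A:    4  0.008
  19 A:    2  0.004
mean Rg = 12.21 A
group  7 A: r_max = 22.9 A
group 19 A: r_max = 62.0 A
Ramachandran region fractions: {'beta': 0.252, 'ppii': 0.304, 'alpha': 0.146, 'lh': 0.029}
```

The 500-frame synthetic ensemble spans Rg ≈ 7–19 Å with a smooth, broad
histogram; the most compact group's maximum internal distance (22.9 Å) is a
third of the most extended group's (62.0 Å) — the compaction trend the
decomposition exists to expose — and the recovered region fractions match
the generator's configured occupancies (0.25 / 0.30 / 0.15 / 0.03).

## Command line

The same workflow runs end-to-end from flat YAML configs:

```sh
coedecomp generate gen.yaml ensemble.pdb      # synthetic ensemble -> multi-MODEL PDB
coedecomp decompose run.yaml                  # full per-group analysis -> out/ + manifest.json
coedecomp compare out/manifest.json exp.dat   # chi^2 of each average profile vs a measured curve
```

`decompose` writes every result as flat text (TSV / 2-3-column curves /
`.ndx` group index files) plus a `manifest.json` with parameters, the seed,
and SHA-256 checksums per file; identical config + seed reproduce identical
checksums.

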