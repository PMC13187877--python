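# vibromap

Normal-mode vibrational energy transport and mechanical stability analysis
for protein structures, at desk scale.

Phosphorylation can rigidify a protein: a covalently attached PO₃²⁻ group
adds mass and a strong polar contact, changing how vibrational energy
flows between residues and how much force the fold withstands.  `vibromap`
provides the complete computational chain for studying this class of
question on harmonic and coarse-grained models:

- **Structures** — PDB read/write with residue bookkeeping, a
  phosphoaspartate patch (PO₃²⁻ on a carboxylate oxygen, ideal geometry,
  −2 e), and region selection.
- **Normal modes** — elastic-network / spring-list Hessians (analytic,
  mass-weighted), staged minimisation (steepest descent → conjugate
  gradient → L-BFGS), eigenmodes in cm⁻¹, and quantum harmonic heat
  capacity C_v = k_B Σ x²eˣ/(eˣ−1)².
- **Energy transport** — Allen–Feldman mode diffusivity
  D_a = (π/dω_a²) Σ_b |S_ab|² g_η(ω_a−ω_b) built from heat-flux matrix
  elements, frequency-band and thermal averaging, residue×residue
  communication maps, temperature-difference maps, VED color
  classification, and an independent wave-packet oracle (direct harmonic
  dynamics of a localized excitation) for validation.
- **Trajectory metrics** — Kabsch superposition, RMSD series, per-residue
  RMSF, salt-bridge and hydrogen-bond detection.
- **Pulling** — constant-velocity steered dynamics of bead-spring models
  with breakable cross-links (Langevin/BAOAB, COM restraint at
  1,500 kJ mol⁻¹ nm⁻², 0.01 nm/ps), force profiles, and rupture analysis.
- **Synthetic generators** — homolog pairs differing only in cross-link
  count (9 vs 2) and a phospho-like modification, and exact harmonic
  trajectories with known per-residue variance, so every stage is testable
  without external data.

The model, numerical conventions, and their limits are documented in
[docs/methods.md](docs/methods.md).

## Worked example

Build a synthetic homolog pair — model A with nine C-terminal cross-links
and a phospho-like site, model B with two and none — then compare energy
transport and unfolding resistance:

```python
import numpy as np
from vibromap import nma, transport, pulling
from vibromap.synthetic import make_homolog_pair

mod_a, mod_b = make_homolog_pair(n_residues=64, strong_links=9, weak_links=2, seed=1)

maps = {}
for tag, model in (("A", mod_a), ("B", mod_b)):
    pot = nma.PotentialModel("pairwise_springs", springs=model.springs)
    hessian = nma.build_hessian(model.structure, pot)
    modes = nma.normal_modes(hessian)
    D = transport.mode_diffusivity(modes, hessian)
    freqs = modes.frequencies_cm[modes.nonzero]
    band = transport.BandSpec(tuple(np.percentile(freqs, np.linspace(10, 90, 6))), 10)
    maps[tag] = transport.communication_map(modes, D, model.structure, band, 300.0, hessian)
    cv = nma.heat_capacity(modes, 300.0)
    print(f"model {tag}: {modes.n_modes - modes.n_zero_modes} internal modes, "
          f"Cv = {cv.quantum:.4f} kcal/mol/K (classical {cv.classical_limit:.4f})")

site, partner = mod_a.phospho_site, mod_a.phospho_partner
print(f"phospho pair ({site}, {partner}) map entry: "
      f"A = {maps['A'].matrix[site, partner]:.4f}, B = {maps['B'].matrix[site, partner]:.4f} Å²/ps")

protocol = pulling.PullProtocol(temperature=300.0, seed=7, max_extension_factor=2.0)
profile, _, events = pulling.run_pull(mod_a.cg, protocol)
print(f"model A pull: {len(events)} ruptures, "
      f"mean rupture force {pulling.rupture_force(profile, events):.0f} kJ/mol/nm")
```

Output:

```
model A: 186 internal modes, Cv = 0.3693 kcal/mol/K (classical 0.3696)
model B: 186 internal modes, Cv = 0.3693 kcal/mol/K (classical 0.3696)
phospho pair (28, 35) map entry: A = 0.1349, B = 0.0000 Å²/ps
model A pull: 9 ruptures, mean rupture force 679 kJ/mol/nm
```

The communication-map entry on the phospho–partner pair is nonzero only in
the modified model: the stiff contact opens a direct energy-transfer
channel between the two residues.  Both heat capacities sit just below the
classical limit of 186·k_B, as they must for a harmonic solid at 300 K.
The nine logged ruptures are the cross-links failing in sequence as the
C-terminal region unzips under load; their mean smoothed restraint force
is the model's characteristic unfolding force.

The same study end-to-end — maps and difference maps at 300 K and 340 K,
VED rankings, RMSD/RMSF from harmonic trajectories, seeded pulls, a
manifest with checksums, and a text report — runs from the CLI:

```sh
vibromap run --out study_out --seed 5
```

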