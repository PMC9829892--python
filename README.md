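# bwsme

Native-ensemble thermodynamics of helical membrane proteins (and soluble
proteins) from a single structure, using the block Wako–Saitô–Muñoz–Eaton
(bWSME) statistical-mechanical model.

Given one PDB structure, `bwsme` enumerates the model's microstate ensemble
and computes partition functions, heat-capacity curves, 1D/2D free-energy
landscapes, residue folding probabilities and stabilities, pairwise
thermodynamic coupling free energies, and in-silico alanine-scanning
mutational responses. It is aimed at structural biologists and biophysicists
who want an ensemble-level, perturbation-ready view of a fold — for example
of a seven-transmembrane (GPCR-like) helix bundle — without running
all-atom simulations.

## The model

Residues are grouped into **blocks** of up to 4 consecutive residues (never
spanning two secondary-structure elements). Each block is folded (1) or
unfolded (0), and the ensemble keeps every configuration with at most two
folded islands:

* **SSA** — one island of folded blocks,
* **DSA** — two non-interacting islands,
* **DSAw/L** — two islands whose native inter-island contacts are formed, at
  the extra entropic cost of fixing the intervening loop.

The total state count is `1 + C(Nb+1, 2) + 2·C(Nb+1, 4)` for `Nb` blocks.
Each microstate has free energy

```
ΔG = ΔG_stab − T·ΔS_conf
ΔG_stab = Σ_pairs n_ij·ξ                                    (van der Waals)
        + Σ_pairs n_ij·ΔC_p^cont·[(T−T_ref) − T·ln(T/T_ref)] (solvation)
        + Σ_charges q_i·q_j·e²·exp(−κr)/(4πε₀·ε·r)          (Debye–Hückel)
```

where `n_ij` counts native heavy-atom contacts (5 Å cutoff, nearest
neighbors included) between residues in folded, mutually active blocks, and
`ΔS_conf` sums per-residue entropies (−10 J mol⁻¹ K⁻¹, an extra
−6.1 J mol⁻¹ K⁻¹ for coil, 0 for proline). The partition function
`Z = Σ exp(−ΔG_i/RT)` yields all observables:

* 1D profile over the reaction coordinate (number of structured blocks):
  `ΔG_b = −RT ln(Z_b/Z)`; 2D landscapes over N-/C-half block counts.
* Residue folding probability `p_i = Σ_k w_k / Z` and stability
  `ΔG_s,i = −RT ln(p_i/(1−p_i))`.
* Heat capacity `C_p = 2RT·dlnZ/dT + RT²·d²lnZ/dT²`; the single free energy
  scale ξ is calibrated so the C_p peak sits at 333 K.
* Coupling free energies from the four sub-ensembles of each residue pair:
  `ΔG₊ = RT ln(Σp_ff/Σp_uf)`, `ΔG₋ = RT ln(Σp_fu/Σp_uu)`,
  `ΔG_c = ΔG₊ − ΔG₋`; residues whose Z-scored mean ΔG_c exceeds 1 are
  "strongly coupled" (fraction f_c).
* Alanine scanning: each site is truncated past Cβ, the ensemble rebuilt
  with otherwise identical parameters, and the ΔG₊ matrix differenced
  against the wild type to give the per-residue response ⟨ΔΔG₊⟩ with
  mutational-response statistics μ and σ.

## Worked example

Everything below runs on a synthetic two-helix bundle generated by the
package itself — no downloads needed:

```python
import numpy as np
from bwsme import *
from bwsme.ensemble_core import calibrate_xi
from bwsme.fixtures import (SyntheticBundleSpec, make_helix_bundle,
                            make_stride_annotation)

spec = SyntheticBundleSpec(n_helices=2, helix_length=12, loop_length=4,
                           packing_radius=3.5, seed=1)
structure = read_structure(make_helix_bundle(spec), "A")
structure = assign_secondary_structure(structure, make_stride_annotation(spec))
contacts = compute_contacts(structure, cutoff=5.0)
charges = assign_charges(structure, pH=7.0, mode="fixed")
partition = partition_into_blocks(structure, block_size=4)

cal = calibrate_xi(partition, contacts, charges, ModelParameters())
ens = compute_partition_function(partition, contacts, charges,
                                 cal.params, 310.0)
p = residue_fold_probabilities(ens)
summary = mean_coupling(coupling_free_energies(ens))
```

Output:

```
28 residues, 7 blocks, 169 microstates, 677 native contacts
calibrated xi = -138.59 J/mol per contact (Cp peak at 333.15 K)
mean residue folding probability at 310 K: 0.834
strongly coupled residues: 4 of 28 (f_c = 0.14)
intermediates at 1 RT threshold: 0
```

Reading: the per-contact energy required for a 333 K melting temperature is
larger in magnitude here than for a fully packed protein because the
synthetic bundle carries only backbone + Cβ atoms and therefore fewer
contacts per residue. At body temperature the bundle is mostly folded
(⟨p⟩ = 0.83), 14% of residues are strongly coupled hubs, and the 1D profile
has no partially structured intermediate separated by ≥ 1 RT barriers.

The same workflows are available from the shell:

```
bwsme fixtures --n-helices 7 --out-prefix bundle
bwsme calibrate run.yaml          # ξ + Cp curve
bwsme profile run.yaml            # profiles, stabilities, intermediates
bwsme landscape run.yaml          # 2D landscape
bwsme couple run.yaml             # coupling matrices, f_c
bwsme alascan run.yaml            # mutational response
```

with a YAML config naming the structure, chain, temperatures, model
parameters and element (helix) definitions. Outputs are TSV/CSV/JSON with
energies in kJ/mol, plus a provenance log; runs are byte-reproducible.

## Scope

The model is native-centric: non-native interactions, kinetics, explicit
membranes/lipids, ligand binding and missing-loop modelling are out of
scope. Users supply complete, single-chain, ligand-free structures. See
`docs/methods.md` for the full model description, parameter table and known
limitations.
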