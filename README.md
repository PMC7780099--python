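# dimerflex

Structural asymmetry, flexibility, interface-network and thermal-stability
analytics for homodimeric enzyme crystal structures.

Cold-active enzymes such as the *Vibrio* alkaline phosphatase dimer owe part
of their catalytic efficiency to surface loops at the subunit interface: a
large loop of one monomer reaches over the active site of the other, tied
down by a hydrogen-bond and salt-bridge network around a central arginine.
Asking what that network does requires four quantitative analyses that this
package implements as one tested pipeline:

1. **Monomer asymmetry.** Superpose monomer B onto monomer A (or a variant
   monomer onto each wild-type monomer) with the SVD-based Kabsch solution —
   the rotation R and translation t minimising Σᵢ‖aᵢ − (R·bᵢ + t)‖² over
   proper rotations — and report the per-residue Cα deviation trace and its
   pooled RMSD.
2. **Flexibility.** Per-residue crystallographic B-factors (Å²), aggregated
   (main-chain mean by default), max-normalized per structure
   (B̂ᵢ = Bᵢ / max B), differenced between structures, with contiguous
   differential regions flagged and percentile-mapped "worm" radii
   (0.30 Å at ≤ 5th percentile → 1.25 Å at ≥ 95th, 0.80 Å mid-score).
3. **Interface networks.** Distance-classed noncovalent edges: strong
   hydrogen bonds (d < 3.0 Å), weak (3.0–5.0 Å), salt bridges (minimum
   cationic–anionic group distance ≤ 5.0 Å), water bridges (one water O
   within 3.4 Å of polar atoms of two residues); censused around a focal
   loop, split intramolecular vs. intersubunit, with active-site (metal
   centroid) separation.
4. **Stability & kinetics.** Arrhenius fit of inactivation rate constants
   (ln k = ln A − Eₐ/RT) with the derived half-inactivation temperature
   T₅₀% = Eₐ·1000 / (R·(ln A − ln(ln 2/1800 s))); two-state melt fit
   (N ⇌ D, linear baselines, Tm at F_U = 0.5); Michaelis–Menten fit
   v = V_max·S/(K_M + S).

A synthetic-data generator (`dimerflex.synthetic`) builds ideal-geometry toy
dimers with planted displacements, B-factor bumps, interactions, metal sites
and waters — every analysis is verifiable offline against ground truth known
by construction. `dimerflex.emulation` configures it into two study-style
reference dimers (intact interface network vs. broken network with raised
distal flexibility).

## Worked example

```python
from dimerflex.emulation import wildtype_dimer_spec, LOOP_RANGE
from dimerflex.synthetic import make_toy_dimer
from dimerflex import superpose_chains, loop_interaction_summary, detect_salt_bridges

model, truth = make_toy_dimer(wildtype_dimer_spec(seed=0))

result, trace = superpose_chains(model, "A", "B")
print(f"pooled mainchain deviation: {trace.rms:.3f} A over {len(trace.entries)} residues")

net = loop_interaction_summary(model, "A", LOOP_RANGE)
print("intra-loop H-bonds:", net.summary["n_intra_loop_hbonds"],
      "(mainchain-mainchain:", net.summary["n_intra_loop_mainchain_mainchain"], ")")
print("intersubunit bonds:", net.summary["n_intersubunit_bonds"])

salt = [e for e in detect_salt_bridges(model) if e.topology == "inter-chain"][0]
print(f"interface salt bridge {salt.partner1.res_label}-{salt.partner2.res_label}: "
      f"{salt.distance:.1f} A")
```

prints

```
pooled mainchain deviation: 0.301 A over 310 residues
intra-loop H-bonds: 12 (mainchain-mainchain: 6 )
intersubunit bonds: 11
interface salt bridge 336-59: 4.9 A
```

The pooled deviation (~0.3 Å) is the near-perfect rotational symmetry of the
dimer with sub-Å planted asymmetry in two loop regions; the loop census
(12 intramolecular strong H-bonds, 6 of them backbone–backbone, plus 11
bonds across the interface including a 4.9 Å Arg–Asp salt bridge) is the
planted interface network recovered by detection.

The same analyses run from the shell:

```bash
dimerflex simulate --preset wildtype --seed 0 --outdir run/
dimerflex compare  --structure run/wildtype_dimer.pdb --chain-a A --chain-b B --outdir run/
dimerflex network  --structure run/wildtype_dimer.pdb --chain A --loop 324:354 --outdir run/
dimerflex stability --csv run/inactivation.csv --outdir run/
```

For user-supplied crystal structures, `dimerflex.validation.validate_dimer`
and `validate_pair` run the same battery on any PDB/mmCIF file.

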