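# noemin

Restrained energy minimization of NMR structure ensembles: the Universal
Force Field (UFF) combined with CYANA-style `.upl` upper-distance
restraints, FIRE minimization, pseudoatom handling and terminus fixing.

The pipeline:

1. **pdb_io** — read/write multi-model PDB ensembles (one shared topology,
   per-model coordinates), normalizing legacy digit-prefixed hydrogen names
   (`1HB` → `HB1`).
2. **perception** — covalent bonds from residue templates for the 20
   standard amino acids plus a covalent-radius distance criterion for
   everything else; UFF atom typing from element + connectivity; terminus
   completion (N-terminal H1–H3, C-terminal OXT); two equilibrium-length
   overrides: carboxylate C–O at 1.25 Å and arginine CZ–N at 1.34 Å.
3. **restraints** — CYANA `.upl` parsing, pseudoatom construction
   (`Q`/`QX`/`QQX` from hydrogen names), upper-limit widening by the r⁻⁶
   degeneracy factor `r = r_p · (N_i·N_j)^(1/6)`, and resolution with
   unmatched entries reported to `restraints.log`.
4. **forcefield** — UFF bond/angle/torsion/inversion/van-der-Waals energies
   with exact analytic forces (no electrostatics; 1-2/1-3 vdW exclusions,
   full 1-4). Parameters ship as `src/noemin/data/uff_params.tsv`.
5. **restraint_force** — flat-bottom restraint potential: force magnitude
   `K·min(v, 5 Å)` for violation `v`, default `K = 198.6 kcal·mol⁻¹·Å⁻¹`,
   pseudoatom forces split evenly over parent hydrogens.
6. **minimizer** — canonical FIRE, per-model, deterministic.
7. **evaluate** — violation tables, a sum-of-squared-violations target
   function (Å²) and an approximate clash count per 1000 atoms.
8. **fixtures** — deterministic toy molecules (acetate, methylguanidinium,
   peptides, diatomics) plus matching `.upl` text, so everything is testable
   offline.

## CLI

```sh
noemin minimize --pdb input.pdb --upl input.upl --out minimized.pdb \
    --scale-k 1.0 --fix-termini --max-steps 5000 --force-tol 0.05 \
    --report-dir reports/
noemin report --pdb input.pdb --upl input.upl --report-dir reports/
```

`minimize` writes the minimized multi-model PDB, `restraints.log`
(unresolved entries), `violations.tsv` and `summary.txt`.

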