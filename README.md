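# qnsmech

Mechanistic analysis toolkit for covalent catalysis in type III polyketide
synthase–like enzymes: finite active-site cluster models, constrained
reaction-coordinate scans, reaction-state contact mapping, dimer-interface
metrics and 1:1 binding-kinetics fitting — with seeded synthetic fixtures
carrying planted ground truth for every capability.

## The scientific problem

Type III polyketide synthases extend a thioester-bound starter through
repeated decarboxylative condensations at a single catalytic cysteine.
Understanding why one such enzyme stalls after a given number of extensions
— and how active-site substitutions change that — requires several
independent lines of evidence:

1. **Energetics.** How high is the barrier for each acyl-transfer /
   condensation step?  Comparing activation energies for successive
   insertions explains chain-length control (a later insertion with a
   barrier ~10 kcal/mol above the first is effectively forbidden).
2. **Steric context.** Which residues cradle the growing intermediate at
   each reaction state, and how does a point mutation (e.g. Ser → Thr,
   Leu → Ala) change those contacts?
3. **Quaternary structure.** The functional unit is a dimer; its interface
   inventory (buried area, salt bridges, hydrogen bonds, nonbonded
   contacts) is part of the structural account.
4. **Binding.** Substrate affinity measured as 1:1 Langmuir kinetics
   (ka, kd, KD = kd/ka) from sensorgram sets.

`qnsmech` implements each step as a small, testable library component, and
pairs every analysis with a synthetic-fixture generator that plants the
answer, so the whole pipeline is verifiable end to end without any
external data.

## What is in the box

| module | capability |
| --- | --- |
| `qnsmech.structures` | PDB/mmCIF I/O (via gemmi), selections, rigid transforms |
| `qnsmech.active_site` | 12 Å cluster extraction, terminus capping, ligand truncation, rigid/mobile partition |
| `qnsmech.scan` | constrained distance scans (0.4 Å coarse / 0.1 Å fine), pluggable energy backends, profile comparison |
| `qnsmech.contacts` | deterministic surface sampling, per-residue contact areas, none/minor/major classes, mutation screening |
| `qnsmech.interface` | SASA, buried interface area, salt bridges, H-bonds, nonbonded and polar contacts |
| `qnsmech.spr` | 1:1 Langmuir simulation and global kinetic fitting |
| `qnsmech.synthetic` | seeded fixture generators with planted-truth manifests |
| `qnsmech.pipeline` | one-config end-to-end run, deterministic outputs |

The public face is the importable API; `examples/` contains one short
narrative script per capability.  A thin `qnsmech` command-line wrapper
covers the shell-friendly parts (fixture generation, CSV fitting, full
pipeline runs): see `qnsmech --help`.

## Worked example

Compare activation energies for a first versus a later chain insertion on
synthetic systems with planted barriers (`examples/02_reaction_scan.py`):

```python
from qnsmech import ScanProtocol, compare_profiles, make_scan_system, run_scan

profiles = []
for label, height in (("first insertion", 40.0), ("later insertion", 50.0)):
    model, backend, manifest = make_scan_system(barrier_height=height, seed=29)
    protocol = ScanProtocol(
        reacting_pair=tuple(manifest.truth["reacting_pair"]),
        covalent_target=manifest.truth["covalent_target_A"],
        start_distance=manifest.truth["start_distance_A"],
    )
    profiles.append((label, run_scan(model, backend, protocol)))
print(compare_profiles(profiles).to_string(index=False))
```

Output:

```
first insertion: planted 40.0, recovered 40.00 kcal/mol at d = 2.59 Å (16 scan points)
later insertion: planted 50.0, recovered 50.00 kcal/mol at d = 2.59 Å (16 scan points)

ranking by activation energy (lowest first):
          label  activation_energy_kcal_mol  reaction_enthalpy_kcal_mol
first insertion                   39.996376                   38.684852
later insertion                   49.995828                   48.478240
```

Fitting binding kinetics to noisy sensorgrams
(`examples/05_spr_kinetics.py`):

```
simulated 5 sensorgrams, concentrations ['2.0e-07', '5.0e-07', '1.0e-06', '2.0e-06', '5.0e-06'] M
ka   = 9.967e+03 /M/s   (true 1.0e+04)
kd   = 9.999e-03 /s     (true 1.0e-02)
Rmax = 119.9 RU       (true 120)
KD   = 1.003e-06 M     (true 1.0e-06)
```

And the planted dimer interface (`examples/04_interface_metrics.py`):

```
buried area per protomer: 8744.8 Å²
salt bridges:             6
hydrogen bonds:           32
nonbonded contacts:       318
```

Every `examples/*.py` script runs standalone in a few seconds and prints
its results; run them from a scratch directory since some write output
files.

## Reproduction

The headline quantities are produced by a single seeded script:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

This runs the main computations — active-site extraction, surface-sampling
accuracy against the analytic sphere, two barrier scans with planted 40
and 50 kcal/mol answers, planted-interface recovery (6 / 32 / 318), and
clean plus 20-replicate noisy kinetic fits — and writes each quantity as
`{"<name>": {"value": ..., "n": ...}}`.  All randomness derives from
`--seed`; the same seed reproduces the same file byte for byte.  The test
suite (`pytest -q`) includes `tests/test_acceptance.py`, which checks the
same properties at fixed tolerances.

See `docs/methods.md` for the model definitions, parameter choices and
numerical methods.
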