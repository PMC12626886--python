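# npckit

A desk-scale Python toolkit for the computational chain behind in situ
nuclear pore complex (NPC) structure determination: subtomogram averaging
with eightfold symmetry handling, pore-geometry estimation, composite
scaffold assembly with stoichiometry accounting, multi-restraint rigid-body
integrative refinement, TM-score structure comparison, and emPAI-based
nucleoporin inventory. Every stage is exercisable on synthetic data, so the
whole pipeline runs in seconds on one CPU with no downloads.

## Modules

| module | what it does |
| --- | --- |
| `npckit.synthetic` | C8 ring complexes between membrane slabs, wedge-degraded noisy subtomograms with known poses, subunit tables at a known pore diameter, replicate peptide tables |
| `npckit.volume` | `DensityVolume`, `Pose`, `WedgeModel`, MRC2014 (mode 2) I/O, trilinear resampling, missing-wedge masks |
| `npckit.sta` | masked wedge-constrained exhaustive-grid alignment, wedge-compensated averaging, Cn symmetry expansion, FSC + 0.143-threshold resolution, iterative refinement, particle cleaning, Fourier binning |
| `npckit.geometry` | per-pore centre by least-squares line intersection, mean radius/diameter with an occupancy ≥ 5 filter, dataset summaries |
| `npckit.scaffold` | ring composition configs (packaged AtNPC default: 20 NUP species; 1 CR / 2 NR Y-complex rings), toy chain placement, C8 composite assembly, stoichiometry tables |
| `npckit.refine` | rigid bodies over a scaffold; EM-fit (coarse-bead Gaussian rendering vs map), soft-sphere clash, connectivity and elastic-network restraints; simulated-annealing Monte Carlo |
| `npckit.compare` | Kabsch superposition, TM-score with the `1.24 (L-15)^(1/3) - 1.8` distance scale, per-domain scoring |
| `npckit.proteomics` | tryptic digestion (cleave after K/R, not before P), emPAI `10^(obs/observable) - 1`, ≥2-peptide replicate presence calls, NUP census, Y-complex overlap |
| `npckit.cli` / `npckit.pipeline` | subcommands per stage plus a deterministic end-to-end `demo` with a versioned JSON report |

Conventions: lengths in Å, isotropic voxels, pore axis = grid axis 2
(nucleoplasm at negative coordinates), tomographic tilt axis = axis 1,
intrinsic ZYZ Euler angles in degrees backed by explicit rotation matrices.
All generators and optimisers take explicit integer seeds; identical
configuration + seeds give byte-identical outputs.

## CLI

```sh
npckit simulate --n-particles 12 --out-dir scratch/sim   # stack + truth table
npckit align scratch/sim/particle_000.mrc scratch/sim/reference.mrc \
    --angular-step 30 --tilt-range -60 60
npckit average scratch/sim/true_poses.tsv --particle-dir scratch/sim \
    --tilt-range -60 60 --out scratch/sim/avg.mrc
npckit fsc scratch/sim/avg.mrc scratch/sim/reference.mrc
npckit geometry subunits.tsv --min-occupancy 5
npckit composite            # default composition -> stoichiometry JSON
npckit refine --seed 1      # packaged toy two-body annealing problem
npckit census               # 31 detected NUPs, 9/10 Y-complex overlap
npckit demo --out-dir scratch/demo   # full pipeline, report.json
```

`npckit demo` runs synthetic generation → alignment/averaging/FSC →
pore geometry → composite scaffold + stoichiometry → rigid-body refinement →
structure comparison → proteomics census, and writes maps (MRC), tables
(TSV) and a deterministic `report.json`.

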