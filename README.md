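# sh2dock

Docking and trajectory analytics for phosphotyrosine-mimetic inhibitors
of the STAT3 SH2 domain — and, more generally, for any anchored flexible
ligand with many rotatable bonds.

STAT3 drives transcription of anti-apoptotic genes in many cancers; its
SH2 domain mediates the dimerization step, and peptidomimetics of the
pTyr-Xaa-Yaa-Gln motif were developed to block it.  Such compounds carry
9–22 rotatable bonds, which defeats one-shot docking.  `sh2dock`
implements the workflow built around that problem:

* **Incremental anchor-constrained docking** (dock–select–grow–dock):
  the phosphate-bearing root fragment is docked first, the best partial
  poses are kept, the ligand grows a few torsions at a time, and every
  selection step uses the anchor-penalized score

  *S* = *w*·‖x_P − x₀‖² + *E*,

  where x_P is the ligand's phosphorus atom, x₀ the center of the
  positively charged phosphate sub-pocket (Lys591, Arg609, Ser611,
  Glu612, Ser613) and *E* the interaction energy.
* **Trajectory analytics** for 1000-frame MD ensembles: mass-weighted
  Kabsch fitting to frame 1, pose-stability RMSF (frame-averaged RMSD to
  frame 1), k-means clustering (k = 5, RMSD metric, medoid
  representatives), and per-residue hydrogen-bond occupancy with the
  50 %-of-frames retention rule.
* **End-point affinity estimation**
  ΔG_bind = ⟨ΔE_MM + ΔG_polar + ΔG_nonpolar⟩ − TΔS over trajectory
  snapshots, schemes A–D (GB or externally supplied PB polar term, with
  or without normal-mode entropy), plus Cheng–Prusoff conversion of
  assay IC50s (Ki = IC50/(1+[probe]/K_d)) and
  ΔG_exp = RT ln K_i, with correlation-versus-simulation-length tables.
* **Binding-mode classification** of bound conformations into the bent
  (C-terminus in sub-pocket-2), extended (sub-pocket-3) and wedged
  (buried between loops 623–629 and 656–668) modes.
* **Synthetic generators** that plant known answers — a keyed toy
  pocket with a planted pose, jittered trajectories with planted
  clusters and scripted hydrogen bonds, affinity tables with a
  calibrated correlation — so the whole pipeline is testable offline.

MD itself is an explicit external hand-off: the package writes docked
complexes and consumes whatever trajectory you supply (multi-model PDB
or plain-text frames).  See `docs/methods.md` for the model details.

## Worked example

```python
import numpy as np
from sh2dock.synthetic_data import make_toy_system, make_planted_trajectory, HBondScriptEntry
from sh2dock.docking import incremental_dock
from sh2dock.molecules import apply_pose
from sh2dock.trajectory_analysis import fit_trajectory, rmsf, cluster_kmeans, detect_hbonds, occupancy

system = make_toy_system(n_rotatable=10, seed=1)
result = incremental_dock(system.ligand, receptor=system.receptor,
                          config=system.docking_config(seed=0))
best = apply_pose(system.ligand, result.best.pose)
rmsd = np.sqrt(np.mean(np.sum((best - system.planted_coords) ** 2, axis=1)))
print(f"best S = {result.best.score_s:.1f}, RMSD to planted pose = {rmsd:.2f} A")

script = [HBondScriptEntry(614, 0.60, system.acceptor_atoms[0]),
          HBondScriptEntry(615, 0.45, system.acceptor_atoms[1])]
traj = make_planted_trajectory(system, n_frames=1000, sigma=0.15,
                               cluster_fractions=(0.3, 0.25, 0.2, 0.15, 0.1),
                               hbond_script=script, seed=7)
fitted = fit_trajectory(traj.traj)
print(f"RMSF = {rmsf(fitted):.3f} A")
table = occupancy(detect_hbonds(fitted), fitted.n_frames)
print(table.as_dict())
```

prints (seeds as above):

```
best S = -71.7, RMSD to planted pose = 0.71 A
RMSF = 2.821 A
{614: 0.6, 615: 0.45}
```

The docking run recovers the planted pose to sub-ångström accuracy; the
RMSF of the five-cluster trajectory reflects the planted cluster spread
on top of the σ = 0.15 Å jitter; the scripted hydrogen-bond occupancies
(0.60 and 0.45) are recovered exactly, and the 50 % rule keeps residue
614 while dropping 615.

A CLI mirrors the stages:

```bash
sh2dock simulate --n-rotatable 10 --seed 1 --out sim/
sh2dock dock --receptor sim/receptor.pdb --ligand sim/ligand.lig --seed 0 --out poses/
sh2dock analyze --traj sim/trajectory.pdb --k 5 --out report/
sh2dock affinity --energies pb.csv --scheme D --experimental exp.csv --out aff/
sh2dock classify --traj sim/trajectory.pdb --anchor-atoms 0 --cterm-atoms 11,12 --out modes/
sh2dock run --config config.yaml
```

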