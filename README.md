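# strokemap

Multivariate lesion-symptom mapping for stroke cohorts: voxelwise
(SVR-VLSM) and connectome-based (SVR-CLSM) support-vector-regression
mapping of behavioral deficits onto lesion anatomy, with nuisance
residualization, permutation-based familywise-error (FWER) correction,
binary disconnectome construction, and a seeded synthetic-cohort
generator so the whole pipeline is testable end to end without any
imaging data.

The package is aimed at researchers relating reading (or other
behavioral) deficits after left-hemisphere stroke to *where* damage is —
at the level of voxels in a common template space and of white-matter
connections between atlas parcels.

## The method

For a cohort of patients with binary lesion masks and behavioral scores,
one analysis asks: damage to which features predicts a worse score, over
and above nuisance variables?

1. **Design.** Voxels lesioned in ≥ 10% of patients (voxel level), or
   connectome edges that are absent in a patient but present in 100% of
   controls (the binary *disconnectome*) and disconnected in > 10% of
   patients (edge level), form a patients × features binary matrix X.
2. **Residualization.** Lesion volume, age, education, and the contrast's
   behavioral control scores are regressed out of *both* X and the target
   y by OLS.
3. **SVR beta map.** An epsilon-insensitive SVR (linear kernel by
   default) of y\* on X\* is back-projected to feature space:
   β = Σᵢ αᵢ xᵢ over support vectors — the primal weight vector. Damage
   is coded 1 and higher y is better, so deficits appear as β < 0;
   inference is one-tailed negative.
4. **Permutation FWER.** The residualized target is shuffled and the
   model refit (seeded, reproducible); pⱼ = (1 + #{β⁽ᵇ⁾ⱼ ≤ βⱼ}) /
   (n_perm + 1). Voxel level: voxels with p < 0.005 form connected
   clusters (26-connectivity), tested against the permutation null of
   maximum cluster size (clusterwise FWER p < 0.05). Edge level:
   single-step maxT correction against the per-permutation minimum beta;
   parcel level: incident-edge aggregates against a max-parcel null.

Five built-in contrasts target reading processes, each controlling the
others: pseudowords | real words (exaggerated lexicality effect), real
words | pseudowords, 1M+MM pseudowords | 0M + real words, MM | 1M + real
words, and 0M | 1M+MM + real words, where 0M/1M/MM index how many learned
spelling-to-sound body mappings a pseudoword has.

The synthetic generator emulates the cohort structure these analyses
assume — 64 patients / 71 controls, left-lateralized contiguous lesions
with lognormal volumes, control connectomes with a minority of unreliable
edges, patient edges severed exactly when the lesion crosses the tract
trajectory, binomial reading accuracy per stimulus class (200 real words,
3 × 20 pseudowords) whose logit degrades with damage to seeded critical
regions/edges — and exports the ground truth for recovery scoring. See
`docs/methods.md` for the full model and its limitations.

## Worked example

`examples/run_clsm.py` seeds a deficit on one connectome edge and runs
the connectome-level analysis:

```text
seeded critical edge: [('L1', 'L2')]
edges analyzed (present in all controls, disconnected in > 10% of patients): 8
  L1-L2: beta -2.480, FWER p 0.002 <- significant
  L1-L3: beta -0.004, FWER p 0.998
  ...
parcel-level aggregation (sum of negative beta parts over incident edges):
parcel  statistic   p_fwer  significant  analyzable  n_incident_edges
    L1   2.484018 0.017964         True        True                 3
    L2   2.573842 0.009980         True        True                 3
    L3   0.082113 0.994012        False        True                 4
```

The seeded edge L1–L2 is the only significant edge (corrected p = 0.002,
the permutation floor at 500 permutations), and its two endpoint parcels
carry the significant parcel-level statistics — the deficit is localized
to exactly the planted connection.

`examples/run_vlsm.py` does the voxelwise analogue with a 100-voxel
critical region and prints the cluster table in reporting convention
(size in cm³, center of mass in mm, clusterwise FWER p):

```text
subjects analyzed: 64, voxels analyzed: 818 (lesioned in >= 10% of patients)
suprathreshold voxels at p < 0.005: 20
 n_voxels  size_cm3  com_x_mm  com_y_mm  com_z_mm  p_cluster  significant
        5     0.040     -15.4       1.0      -2.2   0.001996         True
        5     0.040      -3.8       3.0      -0.6   0.001996         True
        1     0.008     -17.0      -3.0       3.0   0.900200        False
```

Two 5-voxel clusters near the seeded region survive clusterwise
correction (the truth centroid maps to about (−9, 1, 1) mm on this grid);
singleton clusters do not. `examples/simulate_cohort.py` and
`examples/behavioral_contrasts.py` show the generator and the behavioral
score/contrast machinery.

A thin CLI mirrors the library:

```bash
strokemap simulate --seed 1 --out cohort/
strokemap vlsm --masks cohort/masks --cohort cohort/cohort.tsv \
    --contrast pseudowords_vs_realwords --out out_vlsm/
strokemap clsm --connectomes cohort/connectomes --controls cohort/controls \
    --labels cohort/parcels.tsv --cohort cohort/cohort.tsv \
    --contrast pseudowords_vs_realwords --out out_clsm/
```

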