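"""Generate a synthetic stroke cohort and look at what it contains.

The generator produces left-hemisphere lesion masks with lognormal
volumes, control/patient structural connectomes in which a lesion severs
any edge whose tract trajectory it touches, and a behavior table of
binomial reading-accuracy counts per stimulus class.
"""
import numpy as np

from strokemap import CohortParams, lesion_volume_cm3, simulate_cohort

cohort = simulate_cohort(CohortParams(), seed=1)

vols = [lesion_volume_cm3(m) for m in cohort.masks]
print(f"patients: {len(cohort.masks)}, controls: {len(cohort.control_connectomes)}")
print(f"lesion volume (cm^3): mean {np.mean(vols):.2f}, sd {np.std(vols):.2f}, "
      f"range {min(vols):.2f}-{max(vols):.2f}")

n_edges = len(cohort.atlas.trajectories)
cut_counts = [len(v) for v in cohort.truth.severed_edges.values()]
print(f"atlas: {cohort.atlas.n_parcels} parcels, {n_edges} tract trajectories")
print(f"edges severed per patient: mean {np.mean(cut_counts):.1f} of {n_edges}")

df = cohort.cohort_table.patients
pw = (df["PW0M_correct"] + df["PW1M_correct"] + df["PWMM_correct"]) / 60
rw = df["real_word_correct"] / 200
print(f"patient accuracy: real words {rw.mean():.3f}, pseudowords {pw.mean():.3f}")
print("(a null cohort: accuracies reflect only covariates and binomial noise,")
print(" not lesion location — effect weights are 0 by default)")
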