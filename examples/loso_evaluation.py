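"""Leave-one-subject-out evaluation of two feature sets.

Generates a small cohort, extracts the band-energy score and the
MFCC-T/NT features in one pass, and compares their LOSO ROC metrics.
Each subject is scored by an MLP that never saw their data.
"""

import tremorkit as tk

cohort = tk.gen_cohort(n_subjects=6, seed=1, config={"duration_s": 600.0})
ds = tk.build_dataset(cohort, feature_set=["mfcc_tnt", "energy"])

rep_tnt = tk.loso_feature_auc(ds, classifier="mlp", seed=0)
rep_energy = tk.loso_feature_auc(ds.with_features("energy"))

print(f"{len(ds.y)} windows from {len(rep_tnt.per_subject_auc)} subjects\n")
print("subject   AUC(MFCC-T/NT+MLP)   AUC(3-9 Hz energy)")
for sid in rep_tnt.per_subject_auc:
    print(
        f"{sid:8s}  {rep_tnt.per_subject_auc[sid]:.3f}"
        f"                {rep_energy.per_subject_auc[sid]:.3f}"
    )
print(
    f"\nmean AUC: {rep_tnt.mean_auc:.3f} (MFCC-T/NT) vs "
    f"{rep_energy.mean_auc:.3f} (energy threshold)"
)
print(f"mean FPR at 90% sensitivity: {rep_tnt.mean_fpr_at_09:.3f} vs {rep_energy.mean_fpr_at_09:.3f}")
print(
    "\nFeatures computed on the factorized tremor spectrum beat the plain"
    "\nband-energy benchmark, which broadband arm movements can fool."
)
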