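"""Train from 5-minute diary labels with multiple-instance learning.

No window-level labels are used: the MIL loop starts from the unsupervised
tremor-energy ranking, selects the most/least tremor-like windows of each
diary interval according to its 3-level label, and retrains an MLP until a
validation subset stops improving.
"""

import numpy as np

import tremorkit as tk
from tremorkit.evaluate import roc_metrics, weak_agreement, percent_to_weak_label
from tremorkit.mil import mil_train
from tremorkit.models import predict_scores

cohort = tk.gen_cohort(n_subjects=4, seed=3, config={"duration_s": 600.0})
ds = tk.build_dataset(cohort, feature_set="mfcc_tnt")

res = mil_train(ds.entries, ds.X, ds.energies, base="mlp", max_iters=10, seed=0)
scores = predict_scores(res.model, ds.X)
auc, _ = roc_metrics(scores, ds.y)  # ground-truth labels used only to report

pred_labels, given_labels = [], []
for e in ds.entries:
    pct = 100.0 * float(np.mean(scores[e.window_indices] > 0.5))
    pred_labels.append(percent_to_weak_label(pct))
    given_labels.append(e.label)
rho, p = weak_agreement(pred_labels, given_labels)

print(f"{len(ds.entries)} diary entries over {len(ds.y)} windows")
print(f"iterations run until the validation stop: {res.n_iterations_run} "
      f"(model selected from iteration {res.selected_iteration})")
print(f"window-level AUC of the weakly trained model: {auc:.3f}")
print(f"Spearman agreement with the diary labels: rho={rho:.2f} (p={p:.1e})")
print(
    "\nThe loop converges in a handful of iterations; the model was trained"
    "\nwithout any window-level annotation, yet its window scores agree with"
    "\nthe interval-level self reports."
)
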