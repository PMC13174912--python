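"""One turn of the screen - validate - augment discovery loop.

Trains on 100 labelled synthetic structures, ranks a held-out pool of 60
candidates by predicted adsorption enthalpy, draws the stratified
validation sample biased toward strong binders, then folds the validated
labels back into the training set and re-runs the hyperparameter search.
"""

import numpy as np

from calixtda import (
    ImageConfig,
    TrainingSet,
    augment_and_retrain,
    fit,
    rank_candidates,
    stratified_validation_sample,
    synthetic_labels,
    synthetic_structure_set,
)
from calixtda.surrogate import grid_search_one_se

clouds, _, _ = synthetic_structure_set(160, seed=19)
labels, _, X = synthetic_labels(clouds, noise_sd=0.3, seed=19)
cfg_hash = ImageConfig().config_hash()
n_train = 100

hp, _ = grid_search_one_se(X[:n_train], labels[:n_train],
                           np.logspace(-3, 1, 5), np.logspace(-4, 0, 5), seed=19)
model = fit(X[:n_train], labels[:n_train], hp, config_hash=cfg_hash)

pool_ids = [c.id for c in clouds[n_train:]]
ranked = rank_candidates(model, pool_ids, X[n_train:], cfg_hash)
print("top 5 predicted binders (most negative dH first):")
for r in ranked[:5]:
    print(f"  {r.candidate_id}: {r.predicted_dh:+.2f} kcal/mol")

selected = stratified_validation_sample(ranked, counts=(2, 2, 3), seed=19)
print(f"\nvalidation sample: {len(selected)} candidates "
      f"(2 weak / 2 mid / 3 strong strata at -5 and -7 kcal/mol)")

rows = {cid: n_train + i for i, cid in enumerate(pool_ids)}
sel_rows = [rows[r.candidate_id] for r in selected]
mae = np.mean([abs(r.predicted_dh - labels[i]) for r, i in zip(selected, sel_rows)])
print(f"validation MAE vs reference labels: {mae:.2f} kcal/mol")

ts = TrainingSet(ids=[c.id for c in clouds[:n_train]], X=X[:n_train],
                 y=labels[:n_train], provenance=["initial"] * n_train,
                 config_hash=cfg_hash)
_, fm, merged, hp2 = augment_and_retrain(
    ts, [r.candidate_id for r in selected], X[sel_rows], labels[sel_rows],
    alpha_grid=np.logspace(-3, 1, 5), gamma_grid=np.logspace(-4, 0, 5), seed=19,
)
print(f"\nafter augmentation: {merged.n} training rows "
      f"(was {n_train}); refreshed alpha={hp2.alpha:.3g}, gamma={hp2.gamma:.3g}; "
      f"test R2 {fm.mean_test_r2:.3f}")
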