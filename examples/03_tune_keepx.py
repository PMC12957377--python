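"""Choose how many analytes each block may keep by cross-validated BER.

Tunes keepX over a (1..3) x (1..3) grid with subject-grouped five-fold
cross-validation. The printed surface shows the mean +/- SD balanced error
rate per cell; the chosen cell follows the one-standard-error parsimony
rule, so with two strong planted markers per block it settles on one or two
analytes per block rather than dragging in noise.
"""

from longomics import OutcomeBlock, SimConfig, simulate_dataset, tune_keepx
from longomics.pipeline import preprocess_blocks
from longomics.preprocess import median_impute, scale_unit_variance

dataset, truth = simulate_dataset(SimConfig(seed=3))
filtered, _ = preprocess_blocks(dataset)
blocks = {}
for b, X in filtered.items():
    scaled, _ = scale_unit_variance(X)
    blocks[b], _ = median_impute(scaled)
outcome = OutcomeBlock.from_labels(dataset.samples["genotype"].to_numpy())

grid = [{"proteins": (kp,), "metabolites": (km,)}
        for kp in (1, 2, 3) for km in (1, 2, 3)]
cv = tune_keepx(blocks, outcome, grid, dataset.samples["subject_id"].to_numpy(),
                folds=5, repeats=5, seed=11)

print(cv.to_frame().to_string(index=False))
mean, sd = cv.chosen_ber
print(f"\nchosen: {cv.chosen_keepx}  (BER {mean:.3f} +/- {sd:.3f})")
print("planted stable markers:", truth.stable_ids("proteins"),
      truth.stable_ids("metabolites"))
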