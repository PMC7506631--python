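"""Quantify ternary mixtures with a DWT-ANN model on the selected array.

Trains on a tilted 3^3 factorial design (27 samples), selects the network
topology on 11 random test mixtures, and reports the predicted-vs-expected
regression with its elliptical joint confidence region (EJCR) test.
"""

import warnings

import numpy as np

import etongue as et

warnings.filterwarnings("ignore", message="dropping .* degenerate")

specs, roles = et.default_array_specs(4, 2, 2, seed=0)
selected = [s for s in specs if roles[s.sensor_id] == "informative"]

design = et.DesignSpec()  # PA/UA 0-500 uM, AA 0-2000 uM
train_ds = et.simulate_mixture_dataset(
    selected, et.tilted_factorial(design), analytes=design.analytes, seed=2)
test_ds = et.simulate_mixture_dataset(
    selected, et.random_test_points(design), analytes=design.analytes, seed=3)

wavelet = et.WaveletSpec()
fb_train = et.build_feature_blocks(train_ds, wavelet)
fb_test = et.build_feature_blocks(test_ds, wavelet)
print(f"train {fb_train.n_samples} x {fb_train.n_features}, "
      f"test {fb_test.n_samples} x {fb_test.n_features}")

grid = [et.AnnTopology(h, ht, ot)
        for h in (4, 6, 8) for ht in ("purelin", "tansig")
        for ot in ("satlins", "purelin")]
results, best = et.topology_search(fb_train, None, fb_test, None, grid, seed=0)
print("\ntop of the topology ranking (by test RMSE):")
print(results.head(3).to_string(index=False))

pred = et.predict(best, fb_test)
expected = fb_test.concentrations
print("\npredicted vs expected on the test subset:")
for j, analyte in enumerate(fb_test.analytes):
    rc = et.compare_regression(expected[:, j], pred[:, j], confidence=0.95)
    print(f"  {analyte}: slope {rc.slope:.3f} +- {rc.slope_half_ci:.3f}, "
          f"intercept {rc.intercept:.1f} +- {rc.intercept_half_ci:.1f} uM, "
          f"R2 {rc.r_squared:.4f}, RMSE {rc.rmse:.1f} uM, "
          f"EJCR contains (1,0): {rc.contains_ideal}")
_, total = et.nrmse(expected, pred)
print(f"total NRMSE: {total:.4f}")
print("(slope ~1, intercept ~0 and EJCR containment mean the model is "
      "statistically unbiased; NRMSE is a single scale-free error figure)")
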