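"""Simulate a replicate stock-solution campaign with an 8-sensor array.

Builds the default array (4 informative, 2 redundant, 2 noisy sensors),
measures 5 replicates of each 250 µM analyte stock plus buffer blanks,
and prints the dataset shape and one blank-subtracted peak height.
"""

import etongue as et

specs, roles = et.default_array_specs(4, 2, 2, seed=0)
print("sensor roles:")
for sid, role in roles.items():
    print(f"  {sid:10s} {role}")

ds = et.simulate_selection_dataset(specs, stock_uM=250.0, n_replicates=5, seed=1)
print(f"\ndataset: {len(ds)} samples x {len(ds.sensor_roster)} sensors, "
      f"classes {sorted(set(ds.class_labels()))}")

pa = next(s for s in ds if s.class_label == "PA")
blank = next(s for s in ds if s.class_label == "buffer")
h = et.peak_height(pa.voltammograms["ZnO"], blank.voltammograms["ZnO"])
print(f"ZnO blank-subtracted peak height for 250 uM paracetamol: {h:.2f} uA")
print("(peak height = sensitivity x concentration plus measurement noise)")
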