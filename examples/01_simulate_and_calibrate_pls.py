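"""Simulate a two-analyte UV study and calibrate a PLS model.

Builds the 25-mixture five-level calibration design over 5-25 ug/mL,
simulates overlapping Beer-Lambert spectra at bench-noise levels, picks
the latent-variable count by leave-one-out RMSECV, and reports recovery
statistics on the 13-point Latin-hypercube validation set.
"""

import numpy as np

import chemocal as cc

bundle = cc.make_study(seed=42)
print(f"calibration: {bundle.calibration_x.n_samples} mixtures, "
      f"{bundle.calibration_x.n_wavelengths} wavelengths")

curve = cc.loocv(bundle.calibration_x, bundle.calibration_y, max_lv=6)
print("RMSECV per LV:", np.round(curve.rmsecv_per_lv, 4))
print(f"selected {curve.selected_lv} latent variables")

model = cc.fit_pls(bundle.calibration_x, bundle.calibration_y, curve.selected_lv)
pred = np.asarray(cc.predict(model, bundle.validation_lhs_x.absorbance))
truth = bundle.validation_lhs_y.concentrations

report = cc.evaluate_predictions(pred, truth, bundle.calibration_y.component_names)
for comp in report.components:
    print(f"{comp.component}: RMSEP {comp.rmsep:.3f} ug/mL, "
          f"mean recovery {comp.stats.mean_R_pct:.2f}%, "
          f"%RSD {comp.stats.rsd_pct:.2f}, r {comp.stats.r:.4f}")

# RMSEP is the µg/mL error on unseen mixtures; recoveries near 100% with
# %RSD ~1% show the two overlapping analytes are resolved by the model.
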