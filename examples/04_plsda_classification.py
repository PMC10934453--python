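"""Pairwise PLS-DA stress classification on synthetic five-group spectra.

Extracts 200 ROI spectra per group, trains one SNV-pretreated PLS-DA model
per group pair on a stratified 75/25 split, and prints the prediction-set
accuracy table plus the most discriminant wavelengths of the control vs
doubly-stressed model.
"""

from fluocube import PreprocessSpec, SimConfig, top_wavelengths, train_pairwise
from fluocube.calibration import concat_spectra, extract_roi_spectra, flat_field, make_mask
from fluocube.synthetic import generate_dataset

cfg = SimConfig(seed=4)
scenes, _ = generate_dataset(cfg, scenes_per_group=1, seed=4)
parts = []
for sc in scenes:
    cal = flat_field(sc.raw, sc.white, sc.dark)
    parts.append(extract_roi_spectra(cal, make_mask(cal), n=200, seed=4, label=sc.label))
spectra = concat_spectra(parts)

res = train_pairwise(spectra, PreprocessSpec(method="snv"), fraction=0.75, k_max=10, seed=4)
print("prediction-set accuracy (%), lower triangle = group pairs:")
print(res.prediction_table.round(1).to_string())

extreme = next(p for p in res.pairs if set(p.pair) == {"Cg", "MHL-2"})
print(f"\nCg vs MHL-2: k={extreme.n_components} latent variables, "
      f"prediction accuracy {extreme.prediction_accuracy:.1f}%, R2 {extreme.r2:.2f}")
print("discriminant wavelengths (largest |beta|):")
for wl, beta in top_wavelengths(extreme.model, m=4):
    print(f"  {wl:7.2f} nm  beta={beta:+.3f}")
print("Adjacent group pairs (e.g. HL-1 vs MHL-1) are hardest: their emission")
print("signatures differ least, exactly as for mild stress in real leaves.")
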