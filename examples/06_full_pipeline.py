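"""Run the complete analysis pipeline from one config and compare models.

Simulates 5 groups x 2 scenes, calibrates, masks, extracts 400 ROI spectra
per group, computes three ratio models and three pretreated PLS-DA model
families, and prints the final model-comparison table (mean R2/RMSE over all
10 group pairs per family).
"""

from fluocube import PipelineConfig, SimConfig, run_pipeline

cfg = PipelineConfig(
    sim=SimConfig(seed=6),
    scenes_per_group=2,
    n_spectra_per_group=400,
    seed=6,
    out_dir="scratch/example_run",
)
res = run_pipeline(cfg)
print(f"artifacts written to {res.out_dir}/ "
      f"({len(list(res.out_dir.glob('*.csv')))} CSV tables + run.log)")
print("\nmodel comparison (mean over the 10 group pairs):")
print(res.comparison.round(3).to_string(index=False))
print("\nPLS-DA on preprocessed spectra outperforms single-ratio models:")
print("a single band ratio discards most of the 25-band shape information.")
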