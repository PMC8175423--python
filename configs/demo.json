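{
  "out_dir": "scratch/demo_run",
  "seed": 1,
  "scenario": {},
  "clustering": {"k": 17, "linkage": "average"},
  "dapc": {"labels": ["phylum", "trophic_mode", "alt_trophic_mode", "lifestyle", "substrate", "host_type"], "n_rep": 10, "grid_points": 6},
  "integration": {"n_null": 2000, "null_mode": "permute"},
  "biomarkers": {"tasks": ["trophic_mode"], "platforms": ["PTR", "GC"], "subset_grid": [5, 10, 15, 20, 30, 50], "cv_folds": 10}
}
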