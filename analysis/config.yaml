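# Desk-scale configuration for the narrative analysis chain.
# Structural constants (12 runs, 100 Hz, 8 splits) keep their study
# defaults; subject counts, ROI/region sizes and trial counts are scaled
# down so the whole chain runs in a few minutes on one CPU.
out_dir: results/analysis
seed: 7
fmri:
  n_subjects: 6
  rois: [[V1_foveal, 300], [V1_peripheral, 300], [LOC, 240], [pIPS, 240]]
meg:
  n_subjects: 8
  n_trials_per_condition: 48
  epoch_window: [-0.3, 0.7]
  regions: [[early_visual, 12], [occipitotemporal, 12],
            [posterior_parietal, 12]]
decode:
  k_roi: 300
  k_layer: 200
  k_meg: 12
  n_repeats: 1
gc:
  k: 12
stats_params:
  n_perm: 2000
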