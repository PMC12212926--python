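# Desk-scale pipeline configuration: all five waveform spaces at 5 % of the
# full trial schedule, PCA latent space, 5 bootstrap replicates.
spaces: [sine, standard, poisson, double_sine, nested]
trials_scale: 0.05
method: pca
sigma: 0.05
threshold: 0.01
amplitude_threshold: 30.0
n_replicates: 5
sim:
  n_subjects: 4
  session_size: 60
  n_behavior_per_condition: 150
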