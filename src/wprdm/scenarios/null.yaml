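# No association between WMC and any diffusion parameter.
n_participants: 916
trials_easy: 90
trials_hard: 90
trials_undoable: 45
rho_drift_wmc_easy: 0.0
rho_drift_wmc_hard: 0.0
rho_boundary_wmc: 0.0
rt_cutoff: 3.5
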