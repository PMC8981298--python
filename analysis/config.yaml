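# Desk-scale study configuration shared by the numbered analysis drivers.
# Group-level gait profiles and bout-duration laws use the package defaults;
# two monitored days per participant keep the end-to-end run fast while the
# bout counts per duration bin remain representative.
n_pd: 10
n_hc: 10
n_days: 1
master_seed: 20260921
grid: small
classifier_seeds: [0, 1, 2, 3, 4, 5, 6, 7, 8, 9]
anova_levels: [lab, all_wb, gt60]
out_dir: results/run
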