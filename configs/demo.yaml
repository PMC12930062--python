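# Full demo cohort: 2 groups x 8 mice x 2 ROIs x 4 images (2 hemispheres x
# 2 sections) at the 256x256x15 frame, plus the 4-stage behavioral arm.
# Run: synaptopy run-all --config configs/demo.yaml
out_dir: runs/demo
seed: 1
groups: [grp1, grp2]
mice_per_group: 8
images_per_roi: 4
stack_ny: 256
stack_nx: 256
stack_nz: 15
n_pre: 150
n_post: 150
coloc_fraction: 0.5
snr: 5.0
# second group gets a higher planted colocalized fraction
group_coloc_delta: 0.15
rout_q_percent: 1.0
behavior_stages: [SD, CD, CDR, IDS]
omission_prob: 0.01
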