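backbone: {}
backbone_preset: tiny
batch_size: 8
class_names:
- activity
- chasing
- mounting
- feeding
- resting
- disturbance
data_root: data/demo
dropout: 0.5
epochs: 25
gru_hidden: 512
head_variant: pbatn
lr: 0.001
momentum: 0.9
num_segments: 8
optimizer: adam
run_dir: runs/demo
seed: 0
target_size: 64
test_fraction: 0.1
train_val_ratio: 4.0
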