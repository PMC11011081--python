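# pbatn — temporal-shift + attention video behavior recognition

`pbatn` is a self-contained CPU implementation of a clip-level behavior
classifier for fixed-camera animal monitoring (the motivating setting is
breeding surveillance of captive pangolins: six behaviors — activity,
chasing, mounting, feeding, resting, disturbance — where the two breeding
behaviors take labeling precedence). It provides:

* the **PBATn architecture**: a ResNet-50-shaped backbone whose bottleneck
  main path is *temporal shift → 1×1 conv → local self-attention →
  1×1 conv → channel attention*, group-normalized (32 groups), with a
  dropout + FC + segment-consensus head over 8 sampled frames, and the
  **PBAn** ablation (no shift, GRU head);
* the **data pipeline**: class-per-folder clip datasets, 8-segment frame
  sampling, aspect-preserving resize + zero-pad to 224×224, sliding-window
  online collection;
* the **evaluation protocol**: one-vs-rest confusion-matrix metrics
  (accuracy, precision, recall/TPR, FPR, specificity, F1), macro averages
  and mAP, PR curves with balance point, ROC curves with macro/micro
  averaging and AUC;
* a **synthetic six-class clip generator** whose chasing/activity pair is
  discriminable only through temporal order, so the temporal-shift layer's
  contribution is testable end to end without any real video;
* a **CLI** (`pbatn synth|train|eval|infer|cam`) tying it together.

Everything runs on numpy via a small in-package reverse-mode autodiff
engine — no GPU framework required. See `docs/methods.md` for the model,
metric definitions, and the synthetic-data design.

## Worked example

Generate a small synthetic dataset, train the reduced-size model, and
evaluate it:

```bash
pbatn synth --out data/demo --clips-per-class 20 --seed 0 --test-fraction 0.2
# wrote 120 clips under data/demo (train 78 / val 18 / test 24)

pbatn train --data data/demo --run-dir runs/demo --epochs 25 --seed 0
# epoch 25/25  loss 0.4339  train acc 0.857  val acc 0.708  lr 0.0000
# best val accuracy 0.708 at epoch 25; checkpoint in runs/demo

pbatn eval --checkpoint runs/demo/checkpoint.npz --data data/demo \
           --split test --out runs/demo/eval --test-fraction 0.2
# test accuracy 66.67%  mAP 75.56%  report in runs/demo/eval
```

`runs/demo/eval/report.csv` then holds the per-class table (percentages;
the `average` row is the macro average, whose precision column is the
mAP), `report.json` the same plus AUC/BEP summaries, and the PNGs the
PR/ROC curves and confusion heat map. On this run the report reads:

```
class,accuracy,precision,recall,specificity,f1
activity,75.00,33.33,50.00,80.00,40.00
chasing,70.83,20.00,25.00,80.00,22.22
mounting,100.00,100.00,100.00,100.00,100.00
feeding,100.00,100.00,100.00,100.00,100.00
resting,87.50,100.00,25.00,100.00,40.00
disturbance,100.00,100.00,100.00,100.00,100.00
average,88.89,75.56,66.67,93.33,67.04
```

The spatially-cued classes (feeding, disturbance, mounting) are already
solved at this miniature scale, while the temporally-defined
activity/chasing pair — indistinguishable frame by frame by design — is
still confused (and drags resting down with it): that pair is what the
temporal-shift layer has to earn with more data and epochs.
The full-scale check in `tests/test_acceptance.py` (60 clips/class, up
to 30 epochs) reaches ≥ 90 % validation accuracy with the pair separated
well above chance, and collapses back to chance when the shift is
ablated.

Online inference emits one JSON line per sliding window:

```bash
pbatn infer --checkpoint runs/demo/checkpoint.npz --frames stream_dir --fps 30
# {"window": 0, "label": "resting", "probabilities": {...}}
```

and `pbatn cam` writes per-frame class-activation heat maps.

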