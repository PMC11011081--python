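{
  "class_names": [
    "activity",
    "chasing",
    "mounting",
    "feeding",
    "resting",
    "disturbance"
  ],
  "confusion_matrix": [
    [
      2,
      2,
      0,
      0,
      0,
      0
    ],
    [
      3,
      1,
      0,
      0,
      0,
      0
    ],
    [
      0,
      0,
      4,
      0,
      0,
      0
    ],
    [
      0,
      0,
      0,
      4,
      0,
      0
    ],
    [
      1,
      2,
      0,
      0,
      1,
      0
    ],
    [
      0,
      0,
      0,
      0,
      0,
      4
    ]
  ],
  "per_class": {
    "activity": {
      "accuracy": 75.0,
      "precision": 33.33,
      "recall": 50.0,
      "fpr": 20.0,
      "specificity": 80.0,
      "f1": 40.0
    },
    "chasing": {
      "accuracy": 70.83,
      "precision": 20.0,
      "recall": 25.0,
      "fpr": 20.0,
      "specificity": 80.0,
      "f1": 22.22
    },
    "mounting": {
      "accuracy": 100.0,
      "precision": 100.0,
      "recall": 100.0,
      "fpr": 0.0,
      "specificity": 100.0,
      "f1": 100.0
    },
    "feeding": {
      "accuracy": 100.0,
      "precision": 100.0,
      "recall": 100.0,
      "fpr": 0.0,
      "specificity": 100.0,
      "f1": 100.0
    },
    "resting": {
      "accuracy": 87.5,
      "precision": 100.0,
      "recall": 25.0,
      "fpr": 0.0,
      "specificity": 100.0,
      "f1": 40.0
    },
    "disturbance": {
      "accuracy": 100.0,
      "precision": 100.0,
      "recall": 100.0,
      "fpr": 0.0,
      "specificity": 100.0,
      "f1": 100.0
    }
  },
  "macro": {
    "accuracy": 88.89,
    "precision": 75.56,
    "recall": 66.67,
    "fpr": 6.67,
    "specificity": 93.33,
    "f1": 67.04
  },
  "micro_accuracy": 66.67,
  "mAP": 75.56,
  "auc": {
    "activity": 0.8375,
    "chasing": 0.6625,
    "mounting": 1.0,
    "feeding": 1.0,
    "resting": 1.0,
    "disturbance": 1.0,
    "macro": 0.9146,
    "micro": 0.9528
  },
  "bep": {
    "activity": 0.0,
    "chasing": 0.25,
    "mounting": 1.0,
    "feeding": 1.0,
    "resting": 1.0,
    "disturbance": 1.0
  }
}
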