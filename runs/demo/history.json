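{
  "train_loss": [
    1.9686805226586082,
    1.936536799777638,
    1.7319762706756592,
    1.5578670610081067,
    1.4175406694412231,
    1.358602447943254,
    1.237042567946694,
    1.3234496550126509,
    1.212702209299261,
    1.1319280916994268,
    1.0223836465315386,
    0.974924008954655,
    0.8784084699370645,
    0.7083142264322801,
    0.7619470059871674,
    0.6559495438228954,
    0.600988734852184,
    0.5651772889223966,
    0.5440229014916853,
    0.5108180777593092,
    0.543166309595108,
    0.46291823007843713,
    0.48103749548847025,
    0.49000144275751983,
    0.4339498538862575
  ],
  "train_accuracy": [
    0.16666666666666666,
    0.25,
    0.2976190476190476,
    0.2857142857142857,
    0.4166666666666667,
    0.36904761904761907,
    0.5,
    0.4642857142857143,
    0.5119047619047619,
    0.5952380952380952,
    0.6666666666666666,
    0.6547619047619048,
    0.6547619047619048,
    0.7976190476190477,
    0.75,
    0.7857142857142857,
    0.7976190476190477,
    0.8452380952380952,
    0.8214285714285714,
    0.8452380952380952,
    0.8571428571428571,
    0.8690476190476191,
    0.8928571428571429,
    0.8690476190476191,
    0.8571428571428571
  ],
  "val_accuracy": [
    0.16666666666666666,
    0.3333333333333333,
    0.375,
    0.375,
    0.5,
    0.375,
    0.2916666666666667,
    0.375,
    0.5,
    0.5,
    0.5,
    0.5416666666666666,
    0.5,
    0.5,
    0.6666666666666666,
    0.5,
    0.5833333333333334,
    0.7083333333333334,
    0.5416666666666666,
    0.6666666666666666,
    0.7083333333333334,
    0.6666666666666666,
    0.7083333333333334,
    0.6666666666666666,
    0.7083333333333334
  ],
  "best_val_accuracy": 0.7083333333333334,
  "best_epoch": 24,
  "seconds": 145.69451642036438
}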