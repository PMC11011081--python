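2026-09-24 21:58:19,293 pbatn.train INFO epoch 1/25  loss 1.9687  train acc 0.167  val acc 0.167  lr 0.0003
2026-09-24 21:58:24,861 pbatn.train INFO epoch 2/25  loss 1.9365  train acc 0.250  val acc 0.333  lr 0.0007
2026-09-24 21:58:30,395 pbatn.train INFO epoch 3/25  loss 1.7320  train acc 0.298  val acc 0.375  lr 0.0010
2026-09-24 21:58:36,342 pbatn.train INFO epoch 4/25  loss 1.5579  train acc 0.286  val acc 0.375  lr 0.0010
2026-09-24 21:58:42,039 pbatn.train INFO epoch 5/25  loss 1.4175  train acc 0.417  val acc 0.500  lr 0.0010
2026-09-24 21:58:47,277 pbatn.train INFO epoch 6/25  loss 1.3586  train acc 0.369  val acc 0.375  lr 0.0010
2026-09-24 21:58:53,147 pbatn.train INFO epoch 7/25  loss 1.2370  train acc 0.500  val acc 0.292  lr 0.0009
2026-09-24 21:58:58,835 pbatn.train INFO epoch 8/25  loss 1.3234  train acc 0.464  val acc 0.375  lr 0.0009
2026-09-24 21:59:04,851 pbatn.train INFO epoch 9/25  loss 1.2127  train acc 0.512  val acc 0.500  lr 0.0008
2026-09-24 21:59:10,233 pbatn.train INFO epoch 10/25  loss 1.1319  train acc 0.595  val acc 0.500  lr 0.0008
2026-09-24 21:59:15,792 pbatn.train INFO epoch 11/25  loss 1.0224  train acc 0.667  val acc 0.500  lr 0.0007
2026-09-24 21:59:21,321 pbatn.train INFO epoch 12/25  loss 0.9749  train acc 0.655  val acc 0.542  lr 0.0007
2026-09-24 21:59:27,219 pbatn.train INFO epoch 13/25  loss 0.8784  train acc 0.655  val acc 0.500  lr 0.0006
2026-09-24 21:59:32,611 pbatn.train INFO epoch 14/25  loss 0.7083  train acc 0.798  val acc 0.500  lr 0.0005
2026-09-24 21:59:38,029 pbatn.train INFO epoch 15/25  loss 0.7619  train acc 0.750  val acc 0.667  lr 0.0005
2026-09-24 21:59:43,540 pbatn.train INFO epoch 16/25  loss 0.6559  train acc 0.786  val acc 0.500  lr 0.0004
2026-09-24 21:59:50,121 pbatn.train INFO epoch 17/25  loss 0.6010  train acc 0.798  val acc 0.583  lr 0.0003
2026-09-24 21:59:56,109 pbatn.train INFO epoch 18/25  loss 0.5652  train acc 0.845  val acc 0.708  lr 0.0003
2026-09-24 22:00:01,888 pbatn.train INFO epoch 19/25  loss 0.5440  train acc 0.821  val acc 0.542  lr 0.0002
2026-09-24 22:00:08,211 pbatn.train INFO epoch 20/25  loss 0.5108  train acc 0.845  val acc 0.667  lr 0.0002
2026-09-24 22:00:13,917 pbatn.train INFO epoch 21/25  loss 0.5432  train acc 0.857  val acc 0.708  lr 0.0001
2026-09-24 22:00:19,945 pbatn.train INFO epoch 22/25  loss 0.4629  train acc 0.869  val acc 0.667  lr 0.0001
2026-09-24 22:00:25,983 pbatn.train INFO epoch 23/25  loss 0.4810  train acc 0.893  val acc 0.708  lr 0.0000
2026-09-24 22:00:33,076 pbatn.train INFO epoch 24/25  loss 0.4900  train acc 0.869  val acc 0.667  lr 0.0000
2026-09-24 22:00:39,477 pbatn.train INFO epoch 25/25  loss 0.4339  train acc 0.857  val acc 0.708  lr 0.0000
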