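class,accuracy,precision,recall,specificity,f1
activity,75.00,33.33,50.00,80.00,40.00
chasing,70.83,20.00,25.00,80.00,22.22
mounting,100.00,100.00,100.00,100.00,100.00
feeding,100.00,100.00,100.00,100.00,100.00
resting,87.50,100.00,25.00,100.00,40.00
disturbance,100.00,100.00,100.00,100.00,100.00
average,88.89,75.56,66.67,93.33,67.04
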