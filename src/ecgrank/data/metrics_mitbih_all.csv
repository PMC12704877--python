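Method,Auc,f1-score,Accuracy
AEFNN,97.57,99.00,97.96
AEFKNN,92.67,96.00,93.72
AEFRF,91.11,96.00,93.72
AEFSVMR,90.12,95.00,92.27
AEFSVMP,90.12,95.00,92.27
AEFDT,83.37,90.00,86.34
AEFSVML,75.37,88.00,82.52
CFNN,75.11,86.00,79.42
CFSVMR,73.92,86.00,79.33
CFSVMP,73.92,86.00,79.33
CFSVML,73.96,86.00,79.28
CFSVMS,68.90,83.00,75.28
CFKNN,69.66,84.00,72.21
CFDT,65.92,81.00,72.16
CFRF,65.88,81.00,72.14
AEFSVMS,65.15,80.00,71.75
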