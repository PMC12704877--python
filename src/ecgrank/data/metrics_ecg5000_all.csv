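Method,Auc,f1-score,Accuracy
AEFSVMR,99.33,99.00,99.33
AEFSVMP,99.33,99.00,99.33
AEFRF,99.22,99.00,99.20
AEFNN,98.55,99.00,99.20
AEFKNN,98.55,99.00,99.20
AEFSVML,98.32,99.00,98.46
AEFDT,97.92,98.00,97.93
AEFSVMS,91.95,93.00,92.00
CFSVML,82.57,88.00,85.00
CFSVMR,81.97,88.00,84.66
CFSVMP,81.97,88.00,84.66
CFNN,82.33,88.00,84.39
CFKNN,80.50,86.00,77.73
CFRF,76.71,81.00,77.77
CFDT,76.71,81.00,77.77
CFSVMS,73.77,79.00,74.73
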