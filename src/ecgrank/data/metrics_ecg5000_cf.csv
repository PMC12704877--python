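Method,Auc,f1-score,Accuracy
CFSVML,82.57,88,85.00
CFSVMR,81.97,88,84.66
CFSVMP,81.97,88,84.66
CFNN,82.33,88,84.39
CFKNN,80.50,86,77.73
CFRF,76.71,81,77.77
CFDT,76.71,81,77.77
CFSVMS,73.77,79,74.73
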