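Method,Auc,f1-score,Accuracy
CFNN,75.11,86.00,79.42
CFSVMR,73.92,86.00,79.33
CFSVMP,73.92,86.00,79.33
CFSVML,73.96,86.00,79.28
CFSVMS,68.90,83.00,75.28
CFKNN,69.66,84.00,72.21
CFDT,65.92,81.00,72.16
CFRF,65.88,81.00,72.14
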