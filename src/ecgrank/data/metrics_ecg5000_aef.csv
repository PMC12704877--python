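Method,Auc,f1-score,Accuracy
AEFSVMR,99.33,99,99.33
AEFSVMP,99.33,99,99.33
AEFRF,99.22,99,99.20
AEFKNN,98.55,99,99.20
AEFNN,98.55,99,99.20
AEFSVML,98.32,99,98.46
AEFDT,97.92,98,97.93
AEFSVMS,91.95,93,92.00
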