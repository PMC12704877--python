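Method,Auc,f1-score,Accuracy
AEFNN,97.57,99,97.96
AEFKNN,92.67,96,93.72
AEFRF,91.11,96,93.72
AEFSVMR,90.12,95,92.27
AEFSVMP,90.12,95,92.27
AEFDT,83.37,90,86.34
AEFSVML,75.37,88,82.52
AEFSVMS,65.15,80,71.75
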