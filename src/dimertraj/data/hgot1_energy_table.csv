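system,EM_kcal,EM_sd,EE_kcal,EE_sd,EL_kcal,EL_sd,ET_kcal,ET_sd
WT,-42387.29,106.91,-235.72,25.08,-612.16,32.51,-43235.17,88.24
E266K,-41806.95,95.56,-201.54,17.55,-615.90,35.93,-42624.39,87.24
R267H,-42239.94,75.36,-293.19,20.87,-592.63,54.48,-43125.76,67.70
P300L,-41864.23,108.22,-210.21,27.21,-643.83,16.53,-42718.27,94.93
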