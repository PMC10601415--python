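target,auc_pdbfixer,auc_lepro,auc_spruce,ef1_pdbfixer,ef1_lepro,ef1_spruce
adrb2,0.61,0.61,0.78,6.4,6.4,7.8
cp2c9,0.67,0.67,0.6,2.3,2.3,6.4
fa7,0.74,0.75,0.78,39.7,39.7,43.4
fabp4,0.87,0.75,0.87,21,31.8,22.96
gria2,0.67,0.67,0.72,20.8,19,23.9
mcr,0.69,0.69,0.6,16.5,16.5,15
mk01,0.63,0.63,0.82,13.5,13.5,13.9
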