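unit,nisp_identified,mne,mni,grand_total
A2-A1,450,152,32,11086
D3,139,74,21,1821
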