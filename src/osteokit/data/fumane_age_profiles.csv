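unit,group,F,J,SAd,Ad,S
A2-A1,ungulates,1,9,1,12,1
D3,ungulates,0,6,1,8,0
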