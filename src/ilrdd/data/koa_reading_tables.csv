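tp,fp,fn,tn,label
58,40,65,35,T1WI
64,35,59,40,T2WI
70,32,53,43,SE-T2WI
76,30,47,45,FS-T2WI
109,11,14,64,multimodal
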