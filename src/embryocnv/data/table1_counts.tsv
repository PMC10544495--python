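category	arrested	blastocyst
Euploid	17	189
MeioticOnly	66	228
MeioticPlusMitoticOrSeg	141	119
MitoticOnly	32	29
MitoticAndOrSeg	41	47
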