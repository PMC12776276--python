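species: human
dorsal: [TBX5, TBX2, TBX3, ALDH1A1, EFNB2, EFNB1]
ventral: [VAX1, CHRDL1, ALDH1A3]
nasal: [FOXG1, SOHO-1, HMX1, EFNA5, EFNA2]
temporal: [FOXD1, EPHA3]
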