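species: chicken
dorsal: [Tbx5, Tbx2, Tbx3, Aldh1a1, EfnB2, EfnB1]
ventral: [Vax1, Chrdl1, Aldh1a3]
nasal: [FoxG1, SOHo-1, Hmx1, EfnA5, EfnA2]
temporal: [FoxD1, EphA3]
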