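genotype,environment,pot,seeds_planted,seedlings_retained,adults,seeds_produced
A,toy_low_density,pot1,10,1,1,20
A,toy_low_density,pot2,10,1,1,20
A,toy_low_density,pot3,10,1,1,20
A,toy_low_density,pot4,10,1,1,20
A,toy_low_density,pot5,10,1,1,20
A,toy_low_density,pot6,10,1,1,20
A,toy_low_density,pot7,10,1,1,20
A,toy_low_density,pot8,10,1,1,20
A,toy_low_density,pot9,10,1,1,20
A,toy_low_density,pot10,10,1,1,20
A,toy_low_density,pot11,10,1,1,20
A,toy_low_density,pot12,10,1,1,20
A,toy_low_density,pot13,10,1,1,20
A,toy_low_density,pot14,10,1,1,20
A,toy_low_density,pot15,10,1,1,20
A,toy_low_density,pot16,10,1,1,20
A,toy_low_density,pot17,10,1,1,20
A,toy_low_density,pot18,10,1,1,20
A,toy_low_density,pot19,10,1,1,20
A,toy_low_density,pot20,10,1,1,20
A,toy_low_density,pot21,10,1,1,20
A,toy_low_density,pot22,10,1,1,20
A,toy_low_density,pot23,10,1,1,20
A,toy_low_density,pot24,10,1,1,20
A,toy_low_density,pot25,10,1,1,20
A,toy_low_density,pot26,10,1,1,20
A,toy_low_density,pot27,10,1,1,20
A,toy_low_density,pot28,10,1,1,20
A,toy_low_density,pot29,10,1,1,20
A,toy_low_density,pot30,10,1,1,20
A,toy_low_density,pot31,10,1,1,20
A,toy_low_density,pot32,10,1,1,20
A,toy_low_density,pot33,10,1,1,20
A,toy_low_density,pot34,10,1,1,20
A,toy_low_density,pot35,10,1,1,20
A,toy_low_density,pot36,10,1,1,20
A,toy_low_density,pot37,10,1,1,20
A,toy_low_density,pot38,10,1,1,20
A,toy_low_density,pot39,10,1,1,20
A,toy_low_density,pot40,10,1,1,20
A,toy_low_density,pot41,10,1,1,20
A,toy_low_density,pot42,10,1,1,20
A,toy_low_density,pot43,10,1,1,20
A,toy_low_density,pot44,10,1,1,20
A,toy_low_density,pot45,10,1,1,20
A,toy_low_density,pot46,10,1,1,20
A,toy_low_density,pot47,10,1,1,20
A,toy_low_density,pot48,10,1,1,20
A,toy_low_density,pot49,10,1,1,20
A,toy_low_density,pot50,10,1,1,20
A,toy_low_density,pot51,10,1,1,20
A,toy_low_density,pot52,10,1,1,20
A,toy_low_density,pot53,10,1,1,20
A,toy_low_density,pot54,10,1,1,20
A,toy_low_density,pot55,10,1,1,20
A,toy_low_density,pot56,10,1,1,20
A,toy_low_density,pot57,10,1,1,20
A,toy_low_density,pot58,10,1,1,20
A,toy_low_density,pot59,10,1,1,20
A,toy_low_density,pot60,10,1,1,20
A,toy_low_density,pot61,10,1,1,20
A,toy_low_density,pot62,10,1,1,20
A,toy_low_density,pot63,10,1,1,20
A,toy_low_density,pot64,10,1,1,20
A,toy_low_density,pot65,10,1,1,20
A,toy_low_density,pot66,10,1,1,20
A,toy_low_density,pot67,10,1,1,20
A,toy_low_density,pot68,10,1,1,20
A,toy_low_density,pot69,10,1,1,20
A,toy_low_density,pot70,10,1,1,20
A,toy_low_density,pot71,10,1,1,20
A,toy_low_density,pot72,10,1,1,20
A,toy_low_density,pot73,10,1,1,20
A,toy_low_density,pot74,10,1,1,20
A,toy_low_density,pot75,10,1,1,20
A,toy_low_density,pot76,10,1,1,20
A,toy_low_density,pot77,10,1,1,20
A,toy_low_density,pot78,10,1,1,20
A,toy_low_density,pot79,10,1,1,20
A,toy_low_density,pot80,10,1,1,20
A,toy_low_density,pot81,10,1,1,20
A,toy_low_density,pot82,10,1,1,20
A,toy_low_density,pot83,10,1,1,20
A,toy_low_density,pot84,10,1,1,20
A,toy_low_density,pot85,10,1,1,20
A,toy_low_density,pot86,10,1,1,20
A,toy_low_density,pot87,10,1,1,20
A,toy_low_density,pot88,10,1,1,20
A,toy_low_density,pot89,10,1,1,20
A,toy_low_density,pot90,10,1,1,20
A,toy_low_density,pot91,10,1,0,0
A,toy_low_density,pot92,10,1,0,0
A,toy_low_density,pot93,10,1,0,0
A,toy_low_density,pot94,10,1,0,0
A,toy_low_density,pot95,10,1,0,0
A,toy_low_density,pot96,10,1,0,0
A,toy_low_density,pot97,10,1,0,0
A,toy_low_density,pot98,10,1,0,0
A,toy_low_density,pot99,10,1,0,0
A,toy_low_density,pot100,10,1,0,0
B,toy_low_density,pot1,10,1,1,20
B,toy_low_density,pot2,10,1,1,20
B,toy_low_density,pot3,10,1,1,20
B,toy_low_density,pot4,10,1,1,20
B,toy_low_density,pot5,10,1,1,20
B,toy_low_density,pot6,10,1,1,20
B,toy_low_density,pot7,10,1,1,20
B,toy_low_density,pot8,10,1,1,20
B,toy_low_density,pot9,10,1,1,20
B,toy_low_density,pot10,10,1,1,20
B,toy_low_density,pot11,10,1,1,20
B,toy_low_density,pot12,10,1,1,20
B,toy_low_density,pot13,10,1,1,20
B,toy_low_density,pot14,10,1,1,20
B,toy_low_density,pot15,10,1,1,20
B,toy_low_density,pot16,10,1,1,20
B,toy_low_density,pot17,10,1,1,20
B,toy_low_density,pot18,10,1,1,20
B,toy_low_density,pot19,10,1,1,20
B,toy_low_density,pot20,10,1,1,20
B,toy_low_density,pot21,10,1,1,20
B,toy_low_density,pot22,10,1,1,20
B,toy_low_density,pot23,10,1,1,20
B,toy_low_density,pot24,10,1,1,20
B,toy_low_density,pot25,10,1,1,20
B,toy_low_density,pot26,10,1,1,20
B,toy_low_density,pot27,10,1,1,20
B,toy_low_density,pot28,10,1,1,20
B,toy_low_density,pot29,10,1,1,20
B,toy_low_density,pot30,10,1,1,20
B,toy_low_density,pot31,10,1,1,20
B,toy_low_density,pot32,10,1,1,20
B,toy_low_density,pot33,10,1,1,20
B,toy_low_density,pot34,10,1,1,20
B,toy_low_density,pot35,10,1,1,20
B,toy_low_density,pot36,10,1,1,20
B,toy_low_density,pot37,10,1,1,20
B,toy_low_density,pot38,10,1,1,20
B,toy_low_density,pot39,10,1,1,20
B,toy_low_density,pot40,10,1,1,20
B,toy_low_density,pot41,10,1,1,20
B,toy_low_density,pot42,10,1,1,20
B,toy_low_density,pot43,10,1,1,20
B,toy_low_density,pot44,10,1,1,20
B,toy_low_density,pot45,10,1,1,20
B,toy_low_density,pot46,10,1,1,20
B,toy_low_density,pot47,10,1,1,20
B,toy_low_density,pot48,10,1,1,20
B,toy_low_density,pot49,10,1,1,20
B,toy_low_density,pot50,10,1,1,20
B,toy_low_density,pot51,10,1,0,0
B,toy_low_density,pot52,10,1,0,0
B,toy_low_density,pot53,10,1,0,0
B,toy_low_density,pot54,10,1,0,0
B,toy_low_density,pot55,10,1,0,0
B,toy_low_density,pot56,10,1,0,0
B,toy_low_density,pot57,10,1,0,0
B,toy_low_density,pot58,10,1,0,0
B,toy_low_density,pot59,10,1,0,0
B,toy_low_density,pot60,10,1,0,0
B,toy_low_density,pot61,10,1,0,0
B,toy_low_density,pot62,10,1,0,0
B,toy_low_density,pot63,10,1,0,0
B,toy_low_density,pot64,10,1,0,0
B,toy_low_density,pot65,10,1,0,0
B,toy_low_density,pot66,10,1,0,0
B,toy_low_density,pot67,10,1,0,0
B,toy_low_density,pot68,10,1,0,0
B,toy_low_density,pot69,10,1,0,0
B,toy_low_density,pot70,10,1,0,0
B,toy_low_density,pot71,10,1,0,0
B,toy_low_density,pot72,10,1,0,0
B,toy_low_density,pot73,10,1,0,0
B,toy_low_density,pot74,10,1,0,0
B,toy_low_density,pot75,10,1,0,0
B,toy_low_density,pot76,10,1,0,0
B,toy_low_density,pot77,10,1,0,0
B,toy_low_density,pot78,10,1,0,0
B,toy_low_density,pot79,10,1,0,0
B,toy_low_density,pot80,10,1,0,0
B,toy_low_density,pot81,10,1,0,0
B,toy_low_density,pot82,10,1,0,0
B,toy_low_density,pot83,10,1,0,0
B,toy_low_density,pot84,10,1,0,0
B,toy_low_density,pot85,10,1,0,0
B,toy_low_density,pot86,10,1,0,0
B,toy_low_density,pot87,10,1,0,0
B,toy_low_density,pot88,10,1,0,0
B,toy_low_density,pot89,10,1,0,0
B,toy_low_density,pot90,10,1,0,0
B,toy_low_density,pot91,10,1,0,0
B,toy_low_density,pot92,10,1,0,0
B,toy_low_density,pot93,10,1,0,0
B,toy_low_density,pot94,10,1,0,0
B,toy_low_density,pot95,10,1,0,0
B,toy_low_density,pot96,10,1,0,0
B,toy_low_density,pot97,10,1,0,0
B,toy_low_density,pot98,10,1,0,0
B,toy_low_density,pot99,10,1,0,0
B,toy_low_density,pot100,10,1,0,0
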