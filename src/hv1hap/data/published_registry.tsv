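name	profile	standard_accession	priority
A1	C15483T A15627G T15639A C15814T C15912T		1
A17	T15620C A15627G T15639A C15814T C15955T		17
A140	A15627G T15639A C15814T A15931- C15959T T16025C A16033G		140
A171	T15639A C15814T G15848A T16025C		171
A228	A15627G T15639A C15814T A15931- C15959T T16025C A16033G		228
A246	A15553G T15639A C15814T A15931-		246
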