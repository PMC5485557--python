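accession	annotated_haplotype	profile
KM262649.1	A228	A15627G T15639A C15814T A15931- C15959T T16025C A16033G
JF342817.1	A17	A15653G C15814T C15955T
JF342836.1	A171	A15553G T15639A C15814T A15931-
KJ637102.1	Be36_2	C15483T A15627G T15639A C15814T C15912T
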