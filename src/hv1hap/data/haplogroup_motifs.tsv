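haplogroup	sites
B	C15526, T15612, C15632, T15639, G15652, T15800, C15814, C15955
C	C15508, C15526, T15639, T15650, T15800, C15912, C15955
D	T15625, C15632, T15636, T15639, T15800, C15814, T15815, G15848, C15912, C15959
E	C15526, A15553, T15639, G15652, T15800, C15814, C15912, G15938
F	A15490, T15523, T15611, A15627, T15628, T15639, G15652, T15800, C15814, C15912
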