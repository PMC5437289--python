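metabolite	fragment_formula	n_carbons	base_mz
pyruvate	C6H12NO3Si	3	174
lactate	C11H25O3Si2	3	261
alanine	C11H26NO2Si2	3	260
glycine	C10H24NO2Si2	2	246
serine	C16H38NO3Si3	3	390
proline	C13H28NO2Si2	5	286
glutamate	C19H42NO4Si3	5	432
glutamine	C19H43N2O3Si3	5	431
aspartate	C18H40NO4Si3	4	418
succinate	C12H25O4Si2	4	289
fumarate	C12H23O4Si2	4	287
malate	C18H39O5Si3	4	419
citrate	C20H39O6Si3	6	459
alpha-ketoglutarate	C14H28NO5Si2	5	346
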