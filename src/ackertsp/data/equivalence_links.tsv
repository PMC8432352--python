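subtype_a	subtype_b	basis
TSP1-1	TSP4-7	shared_module
TSP3-3	TSP4-2	shared_module
TSP3-1	TSP4-8	shared_module
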