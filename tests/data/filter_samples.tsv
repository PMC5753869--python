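sample	population	role	mean_coverage
A	dom	noncarrier	20
B	dom	noncarrier	20
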