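dataset	observed_paired	observed_unpaired
Eubacteria	20	5
Fungi	38	15
Plants	15	1
Animals	19	8
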