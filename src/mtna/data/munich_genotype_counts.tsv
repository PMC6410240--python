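# dataset: MtnA 3' UTR indel genotype counts, wild-caught D. melanogaster, Munich (Germany), seasonal collections
# columns: collection, n_deldel, n_delnon, n_nonnon
collection	n_deldel	n_delnon	n_nonnon
June 2016	160	31	3
Sept 2016	120	22	1
June 2017	131	25	3
Sept 2017	99	18	1
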