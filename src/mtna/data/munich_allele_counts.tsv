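# dataset: MtnA 3' UTR deletion allele counts by sex, wild-caught D. melanogaster, Munich (Germany)
# n_chromosomes = sampled chromosomes; n_del = deletion alleles (published frequency x chromosomes, rounded)
collection	sex	n_chromosomes	n_del
June 2016	F	224	203
June 2016	M	164	148
Sept 2016	F	192	178
Sept 2016	M	94	84
June 2017	F	144	130
June 2017	M	174	157
Sept 2017	F	176	160
Sept 2017	M	60	56
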