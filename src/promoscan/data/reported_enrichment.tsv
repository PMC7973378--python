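motif	k_fg	K_fg	n_bg	N_bg	expected_enrichment
CACGTG	128	849	3824	34417	1.35692989
CACGTA	212	849	6883	34417	1.24860024
ACGTAT	247	849	8196	34417	1.22168805
ACGTAA	280	849	9370	34417	1.21138938
ACGTGA	224	849	7661	34417	1.18529889
GTCATA	373	849	13259	34417	1.14041621
ATTATC	600	849	21924	34417	1.10942201
ATAGTA	564	849	20635	34417	1.10800049
AATACT	596	849	21847	34417	1.10590997
AATATT	736	849	27066	34417	1.10234886
GGCCCA	110	631	3947	34417	1.52008968
AGTACT	170	631	6900	34417	1.34382737
TACGTA	118	631	5002	34417	1.28671384
GTACTA	235	631	10009	34417	1.28062161
ACGTAA	209	631	9370	34417	1.2166071
GTAGTA	238	631	11059	34417	1.17382878
CTAATA	435	631	20787	34417	1.14140848
TAAGTA	409	631	19684	34417	1.13332274
ATAGTA	426	631	20635	34417	1.12602693
CAATTA	484	631	23958	34417	1.10189054
ACAATA	487	631	24128	34417	1.10090866
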