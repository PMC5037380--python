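# Synthetic placeholder phase gene sets (format example only).
# Supply your own phase<TAB>gene table for real analyses.
G1/S	SYN_G1S_01
G1/S	SYN_G1S_02
G1/S	SYN_G1S_03
G1/S	SYN_G1S_04
G1/S	SYN_G1S_05
G1/S	SYN_G1S_06
G1/S	SYN_G1S_07
G1/S	SYN_G1S_08
G1/S	SYN_G1S_09
G1/S	SYN_G1S_10
S	SYN_S_01
S	SYN_S_02
S	SYN_S_03
S	SYN_S_04
S	SYN_S_05
S	SYN_S_06
S	SYN_S_07
S	SYN_S_08
S	SYN_S_09
S	SYN_S_10
G2	SYN_G2_01
G2	SYN_G2_02
G2	SYN_G2_03
G2	SYN_G2_04
G2	SYN_G2_05
G2	SYN_G2_06
G2	SYN_G2_07
G2	SYN_G2_08
G2	SYN_G2_09
G2	SYN_G2_10
G2/M	SYN_G2M_01
G2/M	SYN_G2M_02
G2/M	SYN_G2M_03
G2/M	SYN_G2M_04
G2/M	SYN_G2M_05
G2/M	SYN_G2M_06
G2/M	SYN_G2M_07
G2/M	SYN_G2M_08
G2/M	SYN_G2M_09
G2/M	SYN_G2M_10
M/G1	SYN_MG1_01
M/G1	SYN_MG1_02
M/G1	SYN_MG1_03
M/G1	SYN_MG1_04
M/G1	SYN_MG1_05
M/G1	SYN_MG1_06
M/G1	SYN_MG1_07
M/G1	SYN_MG1_08
M/G1	SYN_MG1_09
M/G1	SYN_MG1_10
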