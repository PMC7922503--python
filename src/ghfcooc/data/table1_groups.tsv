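# Curated functional groups of glycoside hydrolase families (A-L).
# Groups arise from network modules (source_module M1-M9); three modules
# are subdivided by primary enzyme function: M1 -> A/B, M6 -> G/H, M9 -> K/L.
# GH55 and GH64 are shared by K and L; GH144 belongs to no group.
group_id	ghfs	source_module	function_note
A	GH3,GH5,GH9,GH10,GH16,GH30,GH31,GH43,GH51,GH67,GH115	M1	Widely distributed GHs decomposing bulk lignocellulose components (cellulose, beta-glucan, glucuronoarabinoxylan, xyloglucan)
B	GH2,GH27,GH35,GH36,GH42,GH53,GH78,GH95,GH106,GH127,GH146	M1	Widely distributed GHs debranching pectic polysaccharides, specifically rhamnogalacturonan II
C	GH13,GH77	M2	Decomposition or modification of starch
D	GH1,GH4	M3	Glycosidases
E	GH137,GH138,GH139,GH141,GH142,GH143	M4	Debranching of pectic polysaccharides, specifically rhamnogalacturonan II
F	GH82,GH86,GH117,GH150,GH167	M5	Decomposition of cell wall polysaccharides from red algae and seaweeds
G	GH20,GH109	M6	Decomposition of hexosamine
H	GH29,GH92,GH97,GH125	M6	Alpha-glycosidases
I	GH23,GH102,GH103	M7	Decomposition of peptidoglycan
J	GH28,GH88,GH105,GH154	M8	Decomposition of the main chain of pectic polysaccharides (homogalacturonan, rhamnogalacturonan I and II)
K	GH46,GH55,GH64,GH75,GH87,GH114	M9	Decomposition of fungal cell wall polysaccharides (alpha-1,3-glucan, beta-1,3-glucan, chitosan, polygalactosamine)
L	GH6,GH11,GH12,GH48,GH55,GH62,GH64,GH74	M9	Supplemental GHs of group A for more efficient decomposition of bulk lignocellulose components
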