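# Acid phosphatase (King-Armstrong units) in blood serum for 53 prostate-cancer
# patients; nodal_neg = no nodal involvement (non-diseased, m=33),
# nodal_pos = nodal involvement (diseased, n=20).
value,group
40,nodal_neg
40,nodal_neg
46,nodal_neg
47,nodal_neg
48,nodal_neg
48,nodal_neg
49,nodal_neg
49,nodal_neg
50,nodal_neg
50,nodal_neg
50,nodal_neg
50,nodal_neg
50,nodal_neg
52,nodal_neg
52,nodal_neg
55,nodal_neg
55,nodal_neg
56,nodal_neg
59,nodal_neg
62,nodal_neg
62,nodal_neg
63,nodal_neg
65,nodal_neg
66,nodal_neg
71,nodal_neg
75,nodal_neg
76,nodal_neg
78,nodal_neg
83,nodal_neg
95,nodal_neg
98,nodal_neg
102,nodal_neg
187,nodal_neg
48,nodal_pos
49,nodal_pos
51,nodal_pos
56,nodal_pos
67,nodal_pos
67,nodal_pos
67,nodal_pos
70,nodal_pos
70,nodal_pos
72,nodal_pos
76,nodal_pos
78,nodal_pos
81,nodal_pos
82,nodal_pos
82,nodal_pos
84,nodal_pos
89,nodal_pos
99,nodal_pos
126,nodal_pos
136,nodal_pos
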