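compound	betweenness	degree
α-Thujene	0.03661	14
α-Pinene	0.03661	14
Sabinene	0.00722	8
(−)-β-Pinene	0.00722	8
β-Myrcene	0.00219	3
α-Phellandrene	0.00191	4
α-Terpinene	0.24505	19
p-Cymene	0.05287	13
D-Limonene	0.03661	14
γ-Terpinene	0.00805	8
Isoterpinolene	0.01357	10
Linalool	0.11298	17
Terpinen-4-ol	0.06587	15
α-Terpineol	0.15036	20
β-Elemene	0.00037	2
Timberol	0.01214	9
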