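compound	rt_min	relative_content_pct
D-Limonene	11.452	80.7
γ-Terpinene	11.943	8.8
p-Cymene	11.327	2.5
β-Myrcene	10.597	2.2
α-Pinene	9.328	1.3
Linalool	12.544	1
(−)-β-Pinene	10.335	0.7
α-Terpineol	14.367	0.5
Isoterpinolene	12.477	0.4
Terpinen-4-ol	14.110	0.4
α-Terpinene	11.157	0.3
Timberol	20.077	0.3
Methylcyclopentane	2.560	0.2
α-Thujene	9.177	0.2
β-Elemene	17.091	0.2
Cyclohexane	2.598	0.1
Sabinene	10.243	0.1
α-Phellandrene	10.948	0.1
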