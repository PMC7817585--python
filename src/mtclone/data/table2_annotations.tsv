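variant	NV	AF	DS	printed_gene	printed_aa	printed_pathogenic
m.11529T>C	0.000063	0.0	0.73	MT-ND4	M257T	1
m.1415G>A	0.003988	0.000975	NA	MT-RNR1	NA	0
m.4107C>T	0.002859	0.000499	NA	MT-ND1	NA	0
m.1646T>C	0.000169	0.000048	0.1	MT-TV	NA	0
m.7937T>C	0.0	0.0	0.8	MT-COII	F118L	1
m.6899G>A	0.004346	0.001046	NA	MT-COI	NA	0
m.1982G>A	0.0001088	NA	NA	MT-RNR1	NA	0
m.14207G>A	0.003535	0.000713	0.39	MT-ND6	S20N	0
m.3526G>A	0.000388	0.000048	0.58	MT-ND1	A74T	1
m.3833T>C	0.0	0.0	0.69	MT-ND1	L176P	1
m.16078A>G	0.001111	0.000404	NA	MT-DLoop	NA	0
m.2614T>C	0.0001493	NA	NA	MT-RNR2	NA	0
m.6642A>G	0.0	0.0	0.67	MT-COI	I247V	1
m.9591G>A	0.003358	0.00069	0.55	MT-COIII	V129I	1
m.10628C>T	0.0	0.0	NA	MT-ND4L	NA	0
m.3213A>C	0.001704	NA	NA	MT-RNR2	NA	0
m.13151T>C	0.000101	0.000024	0.22	MT-ND5	L272P	0
m.2233T>C	0.000096165	NA	NA	MT-RNR2	NA	0
m.3117C>T	0.000015872	NA	NA	MT-RNR2	NA	0
m.1743T>C	0.0000000063	NA	NA	MT-RNR2	NA	0
m.3849G>A	0.014177	0.002996	NA	MT-ND1	NA	0
m.2470G>A	0.000143	0.0	NA	MT-RNR2	NA	0
m.11723A>T	0.0	0.0	0.71	MT-ND4	T322S	1
m.15853C>T	0.003306	0.000571	NA	MT-CYB	NA	0
m.1776G>A	0.00000862785	NA	NA	MT-RNR2	NA	0
m.3019G>A	0.000496	0.000048	NA	MT-RNR2	NA	0
m.9525G>A	0.001816	0.000285	0.66	MT-COIII	A107	1
m.12383T>C	0.0	0.0	0.2	MT-ND5	I16T	0
m.11642G>A	0.000003	0.000024	0.82	MT-ND4	A295T	1
m.5070A>G	0.000095	0.000024	0.22	MT-ND2	T201A	0
m.2492G>A	0.0006017671	NA	NA	MT-RNR2	NA	0
m.13633G>A	0.000004	0.0	0.29	MT-ND5	G433S	0
m.3153T>C	0.00000000637	NA	NA	MT-RNR2	NA	0
m.5212T>C	0.0	0.0	0.73	MT-ND2	L248P	1
m.1641G>A	0.000074	0.0	0.05	MT-TV	NA	0
m.3146G>A	0.0003245168	NA	NA	MT-RNR2	NA	0
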