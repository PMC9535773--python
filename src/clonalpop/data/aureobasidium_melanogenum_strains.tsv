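strain_id	collection_id	habitat	habitat_class	location	continent	ploidy
1	EXF-924	ponds on sea ice	other	Svalbard, Norway	Europe	1
2	EXF-926	surface glacial ice	other	Svalbard, Norway	Europe	2(?)
3	EXF-3233	deep sea (4,500 m b.s.l.)	seawater	Japan	Asia	1
4	EXF-3371	soil	other	Thailand	Asia	1
5	EXF-3378	public fountain	tap water	Thailand	Asia	1
6	EXF-3397	endoperitoneal fluid	clinical	Greece	Europe	2
8	EXF-4450	Iskra factory	surface	Slovenia	Europe	2
9	EXF-5590	dishwasher rubber seal	surface	Slovenia	Europe	2
10	EXF-6171	glacial ice	other	Argentina	South America	2
11	EXF-7932	metal drain on the kitchen sink	surface	Sweden	Europe	1
12	EXF-7946	kitchen metal holder for washed dishes	surface	Sweden	Europe	1
13	EXF-8016	bathroom faucet and sink contact	surface	Sweden	Europe	1
14	EXF-8022	refrigerator inner surface	surface	Sweden	Europe	1
15	EXF-8044	kitchen metal holder for washed dishes	surface	Sweden	Europe	1
16	EXF-8258	well water	tap water	Slovenia	Europe	2
17	EXF-9877	tap water	tap water	Slovenia	Europe	2
18	EXF-11403	refrigerator inner surface	surface	Sweden	Europe	2(?)
19	EXF-8492	well water	tap water	Slovenia	Europe	2
20	EXF-8678	well water	tap water	Slovenia	Europe	2
21	EXF-8689	well water	tap water	Slovenia	Europe	2
22	EXF-8695	well water	tap water	Slovenia	Europe	2
23	EXF-8702	well water	tap water	Slovenia	Europe	2
24	EXF-8986	fango mud from Secovlje salterns	other	Slovenia	Europe	2
25	EXF-9262	rubber on kitchen drain	surface	Slovenia	Europe	1
26	EXF-9470	kitchen counter above dishwasher	surface	Slovenia	Europe	2
27	EXF-9272	kitchen strainer basket	surface	Slovenia	Europe	1
28	EXF-9298	plastic mesh on kitchen drain	surface	Slovenia	Europe	2
29	EXF-9304	kitchen strainer basket	surface	Slovenia	Europe	2
30	EXF-9313	kitchen sink	surface	Slovenia	Europe	2
31	EXF-9454	tap water	tap water	Slovenia	Europe	2
32	EXF-9484	kitchen counter above dishwasher	surface	Slovenia	Europe	2
33	EXF-9887	tap water	tap water	Slovenia	Europe	2
34	EXF-9516	kitchen sink drain	surface	Slovenia	Europe	2
35	EXF-9539	kitchen strainer basket	surface	Slovenia	Europe	1
36	EXF-9540	dishwasher door	surface	Slovenia	Europe	2
37	EXF-10064	tap water	tap water	Slovenia	Europe	2
38	EXF-11060	ceiling surface	surface	Slovenia	Europe	2(?)
39	EXF-9875	tap water	tap water	Slovenia	Europe	2
40	EXF-9906	Arthrocnemum sp. plant surface from Secovlje saltern	other	Slovenia	Europe	1
41	EXF-9911	kitchen sink drain	surface	Slovenia	Europe	2
42	EXF-9937	kitchen sink drain	surface	Slovenia	Europe	2
43	EXF-10061	tap water	tap water	Slovenia	Europe	2
44	EXF-10062	tap water	tap water	Slovenia	Europe	2
45	EXF-10066	tap water	tap water	Slovenia	Europe	2
46	EXF-10333	tap water	tap water	Slovenia	Europe	2
47	EXF-10372	air in the National Gallery restoration center	other	Slovenia	Europe	1
48	EXF-10726	integument of a male alate ant of Atta sexdens rubropilosa	other	Brazil	South America	1
49	EXF-11028	water from the aquarium with Proteus anguinus	other	Slovenia	Europe	2
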