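strain_id	collection_id	habitat	habitat_class	location	continent	ploidy
1	EXF-9	brine	brine	Ebre Delta salterns, Spain	Europe	1
2	EXF-12	brine	brine	Santa Pola salterns, Spain	Europe	1
3	EXF-15	brine	brine	Santa Pola salterns, Spain	Europe	1
4	EXF-20	brine	brine	Santa Pola salterns, Spain	Europe	2
5	EXF-152	brine	brine	Secovlje salterns, Slovenia	Europe	2
6	EXF-153	brine	brine	Secovlje salterns, Slovenia	Europe	2
7	EXF-154	brine	brine	Secovlje salterns, Slovenia	Europe	2
8	EXF-156	eye infection of aquarium Spondyliosoma cantharus	clinical	unknown		2
9	EXF-157	kidney of Bufo granulosus	clinical	Brazil	South America	1
10	EXF-161	leaf of Rhizophora mangle	other	Senegal	Africa	2
11	EXF-166	seawater-sprayed marble	other	Delos, Greece	Europe	2
12	EXF-177	Tinea nigra	clinical	France	Europe	1
13	EXF-241	brine	brine	Secovlje salterns, Slovenia	Europe	2
14	EXF-269	brine	brine	Santa Pola salterns, Spain	Europe	2
15	EXF-291	brine	brine	Secovlje salterns, Slovenia	Europe	2
16	EXF-561	brine	brine	Namibia, salterns at the Atlantic coast	Africa	1
17	EXF-2515	brine	brine	salterns, Puerto Rico	North America	1
18	EXF-2516	brine	brine	salterns, Puerto Rico	North America	1
19	EXF-2683	salted fish, Osteoglossum bicirrhosum	other	Brazil	South America	2
20	EXF-2685	brine	brine	Secovlje salterns, Slovenia	Europe	1
21	EXF-2783	brine	brine	Secovlje salterns, Slovenia	Europe	1
22	EXF-2785	brine	brine	Secovlje salterns, Slovenia	Europe	2
23	EXF-3845	brine	brine	Candelaria salterns, Puerto Rico	North America	1
24	EXF-3846	brine	brine	Candelaria salterns, Puerto Rico	North America	1
25	EXF-4716	brine bait	brine	Secovlje salterns, Slovenia	Europe	2
26	EXF-6274	brine	brine	Secovlje salterns, Slovenia	Europe	2
27	EXF-6652	spider web in a cave close to the ocean	cave	Atacama, Chile	South America	2
28	EXF-6663	spider web in a cave close to the ocean	cave	Atacama, Chile	South America	1
29	EXF-8170	brine	brine	Secovlje salterns, Slovenia	Europe	2
30	EXF-8422	biofilm from cheese factory brine	brine	Celje, Slovenia	Europe	2
31	EXF-10304	brine	brine	Secovlje salterns, Slovenia	Europe	2
32	EXF-10508	seawater, depth 25 m	seawater	Italy	Europe	2
33	EXF-10509	seawater, depth 200 m	seawater	Italy	Europe	2
34	EXF-10510	seawater, depth 94 m	seawater	Italy	Europe	2
35	EXF-10511	seawater, depth 25 m	seawater	Italy	Europe	2
36	EXF-10512	seawater, depth 25 m	seawater	Italy	Europe	4
37	EXF-10816	bittern after halite precipitation	bittern	Secovlje salterns, Slovenia	Europe	2
38	EXF-10819	bittern after halite precipitation	bittern	Secovlje salterns, Slovenia	Europe	2
39	EXF-10820	bittern after halite precipitation	bittern	Secovlje salterns, Slovenia	Europe	1
40	EXF-10843	brine	brine	Secovlje salterns, Slovenia	Europe	2
41	EXF-10904	bittern after halite precipitation	bittern	Secovlje salterns, Slovenia	Europe	2
42	EXF-10907	bittern after halite precipitation	bittern	Secovlje salterns, Slovenia	Europe	2
43	EXF-10919	bittern after halite precipitation	bittern	Secovlje salterns, Slovenia	Europe	2
44	EXF-10958	bittern after halite precipitation	bittern	Secovlje salterns, Slovenia	Europe	1
45	EXF-10974	brine	brine	Secovlje salterns, Slovenia	Europe	2
46	EXF-11540	sand in a cave close to the ocean	cave	Atacama, Chile	South America	2
47	EXF-11650	sand in a cave close to the ocean	cave	Atacama, Chile	South America	2
48	EXF-11651	sand in a cave close to the ocean	cave	Atacama, Chile	South America	1
49	EXF-12619	coral or deep sea	seawater	China	Asia	1
50	EXF-12620	coral or deep sea	seawater	China	Asia	2
51	EXF-14591	plankton tow	seawater	Vineyard Sound, USA	North America	2
52	EXF-14592	plankton tow	seawater	Vineyard Sound, USA	North America	1
53	EXF-225	malt extract medium, 25% NaCl (w/v)	other	long-term experimental evolution		2
54	EXF-14590	marine	seawater	List on Sylt, Germany	Europe	2
A	EXF-2000	brine	brine	Secovlje salterns, Slovenia	Europe	2
B	EXF-120	brine	brine	Santa Pola saltpans, Spain	Europe	2
C	EXF-562	soil on the sea coast	other	Namibia	Africa	1
D	EXF-2788	brine	brine	Secovlje salterns, Slovenia	Europe	1
E	EXF-171	keratomycosis	clinical	Brazil	South America	2
F	EXF-2682	Trichomycosis nigra	clinical	Italy	Europe	2
G	EXF-10513	deep seawater	seawater	Italy	Europe	2
H	EXF-151	Tinea nigra	clinical	Portugal	Europe	2
I	EXF-6651	spider web in a cave close to the ocean	cave	Atacama, Chile	South America	2
J	EXF-6669	spider web in a cave close to the ocean	cave	Atacama, Chile	South America	2
K	EXF-6654	spider web in a cave close to the ocean	cave	Atacama, Chile	South America	2
L	EXF-6656	rock wall in a cave close to the ocean	cave	Atacama, Chile	South America	2
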