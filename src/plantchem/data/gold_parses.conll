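# Hand-built gold dependency parses (Stanford basic dependencies) for the
# worked-example sentences of the rule development corpus, plus four
# documented model-error sentences.  Columns: index, form, head (0 = root),
# deprel.  The "# id =" comment names the rule structure each block
# exemplifies.

# id = V1
# text = Pomegranate derived from the tree Punica granatum contains anthocyanins.
1	Pomegranate	8	nsubj
2	derived	1	partmod
3	from	2	prep
4	the	5	det
5	tree	3	pobj
6	Punica	7	nn
7	granatum	5	appos
8	contains	0	root
9	anthocyanins	8	dobj
10	.	8	punct

# id = V2
# text = About 450 mg of FB1 were obtained from 800 g cultured corn.
1	About	2	quantmod
2	450	3	num
3	mg	7	nsubjpass
4	of	3	prep
5	FB1	4	pobj
6	were	7	auxpass
7	obtained	0	root
8	from	7	prep
9	800	10	num
10	g	12	nn
11	cultured	12	amod
12	corn	8	pobj
13	.	7	punct

# id = V3
# text = The volatile oil (2-3 %) of ginger consists of mainly mono and sesquiterpenes.
1	The	3	det
2	volatile	3	amod
3	oil	10	nsubj
4	(	6	punct
5	2-3	6	num
6	%	3	dep
7	)	6	punct
8	of	3	prep
9	ginger	8	pobj
10	consists	0	root
11	of	10	prep
12	mainly	13	advmod
13	mono	11	pobj
14	and	13	cc
15	sesquiterpenes	13	conj
16	.	10	punct

# id = P1
# text = Switchgrass as a sole carbon (C) source.
1	Switchgrass	0	root
2	as	1	prep
3	a	9	det
4	sole	9	amod
5	carbon	9	nn
6	(	7	punct
7	C	5	appos
8	)	7	punct
9	source	2	pobj
10	.	1	punct

# id = P2
# text = Saponins from the flowers of Panax notoginseng.
1	Saponins	0	root
2	from	1	prep
3	the	4	det
4	flowers	2	pobj
5	of	4	prep
6	Panax	7	nn
7	notoginseng	5	pobj
8	.	1	punct

# id = R1
# text = Anthocyanins isolated from black soybean seed coat.
1	Anthocyanins	0	root
2	isolated	1	partmod
3	from	2	prep
4	black	5	amod
5	soybean	7	nn
6	seed	7	nn
7	coat	3	pobj
8	.	1	punct

# id = R2
# text = With thermally degraded Feverfew powder containing less contents of parthenolide no built-up antiserotonergic responses were observed after one month.
1	With	16	prep
2	thermally	3	advmod
3	degraded	5	amod
4	Feverfew	5	nn
5	powder	1	pobj
6	containing	5	partmod
7	less	8	amod
8	contents	6	dobj
9	of	8	prep
10	parthenolide	9	pobj
11	no	14	det
12	built-up	14	amod
13	antiserotonergic	14	amod
14	responses	16	nsubjpass
15	were	16	auxpass
16	observed	0	root
17	after	16	prep
18	one	19	num
19	month	17	pobj
20	.	16	punct

# id = A1
# text = Whereas that in PD is soybean oil, a source of unsaturated fatty acids.
1	Whereas	7	mark
2	that	7	nsubj
3	in	2	prep
4	PD	3	pobj
5	is	7	cop
6	soybean	7	nn
7	oil	0	root
8	,	7	punct
9	a	10	det
10	source	7	appos
11	of	10	prep
12	unsaturated	14	amod
13	fatty	14	amod
14	acids	11	pobj
15	.	7	punct

# id = A2
# text = Delta9-tetrahydrocannabinol (THC), the major active component of marijuana.
1	Delta9-tetrahydrocannabinol	0	root
2	(	3	punct
3	THC	1	appos
4	)	3	punct
5	,	1	punct
6	the	9	det
7	major	9	amod
8	active	9	amod
9	component	1	appos
10	of	9	prep
11	marijuana	10	pobj
12	.	1	punct

# id = C1
# text = Haematococcus pluvialis is one of the potent organisms for production of astaxanthin.
1	Haematococcus	2	nn
2	pluvialis	4	nsubj
3	is	4	cop
4	one	0	root
5	of	4	prep
6	the	8	det
7	potent	8	amod
8	organisms	5	pobj
9	for	8	prep
10	production	9	pobj
11	of	10	prep
12	astaxanthin	11	pobj
13	.	4	punct

# id = C2
# text = The calcium contents were the highest in the papaya.
1	The	3	det
2	calcium	3	nn
3	contents	6	nsubj
4	were	6	cop
5	the	6	det
6	highest	0	root
7	in	6	prep
8	the	9	det
9	papaya	7	pobj
10	.	6	punct

# id = CN1
# text = To study the protective effect of panax notoginseng saponins (PNS).
1	To	2	aux
2	study	0	root
3	the	5	det
4	protective	5	amod
5	effect	2	dobj
6	of	5	prep
7	panax	9	nn
8	notoginseng	9	nn
9	saponins	6	pobj
10	(	11	punct
11	PNS	9	appos
12	)	11	punct
13	.	2	punct

# id = FP_EXTRACT
# text = The dichloromethane extract of Feverfew inhibited platelet aggregation.
1	The	3	det
2	dichloromethane	3	nn
3	extract	6	nsubj
4	of	3	prep
5	Feverfew	4	pobj
6	inhibited	0	root
7	platelet	8	nn
8	aggregation	6	dobj
9	.	6	punct

# id = FP_TREATMENT
# text = Ammonia treatment of rice straw improved its storage.
1	Ammonia	2	nn
2	treatment	6	nsubj
3	of	2	prep
4	rice	5	nn
5	straw	3	pobj
6	improved	0	root
7	its	8	poss
8	storage	6	dobj
9	.	6	punct

# id = FN_SPECIFIC
# text = The formation of tobacco-specific nitrosamines was studied.
1	The	2	det
2	formation	7	nsubjpass
3	of	2	prep
4	tobacco-specific	5	amod
5	nitrosamines	3	pobj
6	was	7	auxpass
7	studied	0	root
8	.	7	punct

# id = FN_BRACKET
# text = The aroma compound 3-(methylthio)propanal (cooked potato) was identified.
1	The	4	det
2	aroma	4	nn
3	compound	4	nn
4	3-(methylthio)propanal	10	nsubjpass
5	(	7	punct
6	cooked	7	amod
7	potato	4	dep
8	)	7	punct
9	was	10	auxpass
10	identified	0	root
11	.	10	punct
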