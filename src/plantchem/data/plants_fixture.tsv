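# Fixture plant gazetteer: every plant surface form used by the worked
# examples and the synthetic generator.  Identifiers are NCBI Taxonomy ids
# where well known, else NA.
Pomegranate	Taxonomy:22663
Punica granatum	Taxonomy:22663
ginger	Taxonomy:94328
switchgrass	Taxonomy:38727
Panax notoginseng	Taxonomy:44586
black soybean	Taxonomy:3847
soybean	Taxonomy:3847
soybean oil	NA
Feverfew	Taxonomy:105608
marijuana	Taxonomy:3483
Haematococcus pluvialis	Taxonomy:44745
papaya	Taxonomy:3649
corn	Taxonomy:4577
masson pine	Taxonomy:88728
Pinus massoniana	Taxonomy:88728
rice	Taxonomy:4530
tobacco	Taxonomy:4097
potato	Taxonomy:4113
aloe	Taxonomy:130432
cucumber	Taxonomy:3659
tomato	Taxonomy:4081
blackberries	NA
blueberries	NA
Ginkgo biloba	Taxonomy:3311
kiwifruit	Taxonomy:3625
snapdragon	Taxonomy:4151
Cruciferae	Taxonomy:3700
Cimicifuga racemosa	Taxonomy:64695
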