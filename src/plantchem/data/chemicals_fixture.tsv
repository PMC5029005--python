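# Fixture chemical gazetteer: chemical surface forms used by the worked
# examples and the synthetic generator.  MeSH tree-less descriptor ids where
# well known, else NA.
anthocyanins	MeSH:D000872
Anthocyanins	MeSH:D000872
anthocyanin	MeSH:D000872
FB1	CAS:116355-83-0
sesquiterpenes	MeSH:D012717
carbon	MeSH:D002244
Saponins	MeSH:D012503
saponins	MeSH:D012503
parthenolide	CAS:20554-84-1
fatty acids	MeSH:D005227
Delta9-tetrahydrocannabinol	MeSH:D013759
astaxanthin	CAS:472-61-7
calcium	MeSH:D002118
nitrogen	MeSH:D009584
ammonia	MeSH:D000641
dichloromethane	CAS:75-09-2
methanol	MeSH:D000432
ethanol	MeSH:D000431
chloroform	MeSH:D002725
isopropanol	CAS:67-63-0
nitrosamines	MeSH:D009602
3-(methylthio)propanal	CAS:3268-49-3
emodin	CAS:518-82-1
actinidin	NA
bilobalide	CAS:33570-04-6
methyl bromide	CAS:74-83-9
allyl isothiocyanate	CAS:57-06-7
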