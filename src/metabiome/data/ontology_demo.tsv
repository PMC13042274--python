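# Synthetic demonstration ontology dictionary (CURIE -> label).  These
# code/label pairs are invented stand-ins for the consolidated ENVO/FOODON/
# NCBITaxon/PO/UBERON exports, bundled so the translation step is testable
# offline; production dictionaries are user-supplied.
ENVO:0000001	agricultural soil
ENVO:0000002	river water
ENVO:0000003	rhizosphere
ENVO:0000004	forest soil
ENVO:0000005	sea water
ENVO:0000006	wastewater
ENVO:0000007	sediment
ENVO:0000008	air
ENVO:0000009	bioreactor
ENVO:0000010	freshwater lake
FOODON:0000001	fermented food product
FOODON:0000002	raw milk
NCBITaxon:9606	Homo sapiens
NCBITaxon:9913	Bos taurus
NCBITaxon:4577	Zea mays
PO:0000001	leaf
PO:0000002	root
UBERON:0000001	gut
UBERON:0000002	skin
UBERON:0000003	rumen
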