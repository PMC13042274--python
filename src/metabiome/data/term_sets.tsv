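# Default environment-specific term sets for the keyword-based baseline
# classifier.  Small, hand-written demonstration whitelists; production term
# sets are user-supplied.  Columns: biome <TAB> keyword.
animal	host
animal	gut
animal	feces
animal	fecal
animal	rumen
animal	human
animal	mouse
animal	cow
animal	chicken
animal	pig
animal	skin
animal	intestine
animal	patient
animal	saliva
animal	cecum
animal	insect
plant	leaf
plant	banana
plant	tree
plant	crop
plant	rhizosphere
plant	root
plant	maize
plant	wheat
plant	olive
plant	phyllosphere
plant	seed
plant	grape
plant	leaves
water	river
water	lake
water	sea
water	ocean
water	marine
water	wastewater
water	freshwater
water	brine
water	estuary
water	groundwater
water	sediment
water	seawater
soil	soil
soil	agricultural
soil	forest
soil	tundra
soil	desert
soil	peatland
soil	farmland
soil	paddy
soil	grassland
other	bioreactor
other	laboratory
other	urban
other	air
other	food
other	feed
other	fungus
other	mock
other	reactor
other	indoor
other	fermentation
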