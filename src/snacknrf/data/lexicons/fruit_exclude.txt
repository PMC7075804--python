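# Exclusion terms checked before any fruit/vegetable/nut inclusion term.
# Concentrated juices act as sweeteners, and jam/pectin/flavor forms are
# not fruit; none of these earn first-ingredient or FVN credit.
concentrate
concentrated
concentrates
jam
jams
jelly
pectin
pectins
flavor
flavors
flavour
flavours
flavoring
flavouring
leather
powder
syrup
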