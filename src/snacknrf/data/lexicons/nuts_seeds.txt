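# Nut and seed inclusion terms; peanuts and seeds count toward FVN.
# Whole-word matching keeps "coconut" and "nutmeg" from matching "nut".
almond
almonds
brazil nut
brazil nuts
cashew
cashews
chia seed
chia seeds
flaxseed
flaxseeds
hazelnut
hazelnuts
macadamia
macadamias
nut
nuts
peanut
peanuts
pecan
pecans
pine nut
pine nuts
pistachio
pistachios
pumpkin seed
pumpkin seeds
sesame seed
sesame seeds
sunflower seed
sunflower seeds
walnut
walnuts
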