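# Fruit inclusion terms (whole fruits and purees).  Whole-word matching:
# "apple puree" and "dried apricots" match via their fruit noun; the
# generic term "fruit" catches compound names such as "red fruit".
# Exclusions (concentrates, jams, pectins, flavors) live in
# fruit_exclude.txt and are checked first.
fruit
fruits
apple
apples
apricot
apricots
banana
bananas
blackberry
blackberries
blackcurrant
blackcurrants
blueberry
blueberries
cherry
cherries
clementine
clementines
cranberry
cranberries
date
dates
fig
figs
grape
grapes
grapefruit
kiwi
lemon
lemons
lime
limes
mango
mangoes
melon
nectarine
nectarines
orange
oranges
papaya
peach
peaches
pear
pears
pineapple
plum
plums
prune
prunes
raisin
raisins
raspberry
raspberries
strawberry
strawberries
sultana
sultanas
tangerine
tangerines
watermelon
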