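# Vegetable inclusion terms.  Starchy vegetables (potato, corn) are
# deliberately absent: as chips they never qualify, and outside chip
# categories the conservative default still excludes them.  Legumes other
# than peanuts are also absent by default.
beet
beetroot
broccoli
butternut squash
carrot
carrots
cauliflower
celery
cucumber
kale
pepper
peppers
pumpkin
spinach
squash
tomato
tomatoes
zucchini
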