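# Dairy-first inclusion terms: the rule counts only milk, yogurt, or cheese
# as a qualifying first ingredient.  Whole-word matching means qualified
# variants ("whole milk", "skim milk", "low fat milk", "greek yogurt",
# "cheddar cheese") match through their head noun.
# NOTE: cream is deliberately absent — the rule enumerates milk, yogurt,
# and cheese only, so cream-first ice creams are not dairy-first.
milk
yogurt
yoghurt
cheese
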