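# Dairy exclusion terms, checked before inclusion terms: derived milk
# solids and confectionery do not qualify as dairy.
milk chocolate
milk powder
milk solids
milk protein concentrate
condensed milk
evaporated milk
milk fat
milkfat
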