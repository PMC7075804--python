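# Terms accepted as a leading water ingredient for the fruit-second-after-
# water allowance ("water, oranges").
water
spring water
filtered water
carbonated water
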