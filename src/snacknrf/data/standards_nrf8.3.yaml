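# Shipped NRF8.3 reference standards: US daily values (DV) for the eight
# qualifying nutrients and maximum recommended values (MRV) for the three
# nutrients to limit, applied uniformly across markets.  Editing this file
# (or supplying another like it) defines a different NRFn.3 variant; the
# qualifying set may hold 1-15 nutrients.
qualifying:
  protein: {amount: 50, unit: g}
  fiber: {amount: 28, unit: g}
  vitamin_a: {amount: 800, unit: ug}
  vitamin_c: {amount: 80, unit: mg}
  vitamin_d: {amount: 15, unit: ug}
  calcium: {amount: 1000, unit: mg}
  iron: {amount: 18, unit: mg}
  potassium: {amount: 4700, unit: mg}
limiting:
  added_sugar: {amount: 50, unit: g}
  saturated_fat: {amount: 20, unit: g}
  sodium: {amount: 2400, unit: mg}
total_sugar_mrv: 50
cap: 100
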