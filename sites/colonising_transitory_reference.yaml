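site_name: colonising_transitory_reference
latitude: -27.0
climate: temperate
tidal: subtidal
meadow_type: transitory
life_history: colonising
genus_label: Halophila
light_p:
- 0.8
- 0.766506
- 0.675
- 0.55
- 0.425
- 0.333494
- 0.3
- 0.333494
- 0.425
- 0.55
- 0.675
- 0.766506
reference_value: 100.0
reference_units: shoots per m2
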