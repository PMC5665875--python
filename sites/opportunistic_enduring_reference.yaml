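site_name: opportunistic_enduring_reference
latitude: -27.0
climate: temperate
tidal: subtidal
meadow_type: enduring
life_history: opportunistic
genus_label: Zostera
light_p:
- 0.92
- 0.910622
- 0.885
- 0.85
- 0.815
- 0.789378
- 0.78
- 0.789378
- 0.815
- 0.85
- 0.885
- 0.910622
reference_value: 100.0
reference_units: shoots per m2
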