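[
  {"taxon": "Neanderthal_Altai", "protein_id": "COL4A5", "start": 1264, "end": 1270, "action": "delete"},
  {"taxon": "Neanderthal_Vindija", "protein_id": "COL4A5", "start": 1264, "end": 1270, "action": "delete"},
  {"taxon": "Neanderthal_Chagyrskaya", "protein_id": "COL4A5", "start": 1264, "end": 1270, "action": "delete"},
  {"taxon": "Pan_troglodytes", "protein_id": "COL4A5", "start": 1264, "end": 1270, "action": "delete"},
  {"taxon": "Human", "protein_id": "COL11A1", "start": 261, "end": 313, "action": "delete"},
  {"taxon": "Neanderthal_Altai", "protein_id": "COL11A1", "start": 261, "end": 313, "action": "delete"},
  {"taxon": "Neanderthal_Vindija", "protein_id": "COL11A1", "start": 261, "end": 313, "action": "delete"},
  {"taxon": "Neanderthal_Chagyrskaya", "protein_id": "COL11A1", "start": 261, "end": 313, "action": "delete"},
  {"taxon": "Denisovan", "protein_id": "COL11A1", "start": 261, "end": 313, "action": "delete"},
  {"taxon": "Gorilla_gorilla", "protein_id": "COL11A1", "start": 261, "end": 313, "action": "delete"},
  {"taxon": "Pan_troglodytes", "protein_id": "COL11A1", "start": 261, "end": 313, "action": "delete"},
  {"taxon": "Pongo_abelii", "protein_id": "COL11A1", "start": 261, "end": 313, "action": "delete"},
  {"taxon": "Gorilla_gorilla", "protein_id": "COL18A1", "start": 220, "end": 454, "action": "insert_unknowns"},
  {"taxon": "Gorilla_gorilla", "protein_id": "COL27A1", "start": 3, "end": 21, "action": "mask"}
]
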