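{
  "name": "paper_table1_electrical_scaled",
  "geometry": {
    "dimension": 1,
    "bath_extent": 1.5e-06,
    "gel_shape": "interval",
    "gel_extent": 2.5e-07,
    "refinement_band": 2e-07,
    "base_resolution": 3e-08,
    "refined_resolution": 2e-09
  },
  "fixed_charge": {
    "concentration": 2.0,
    "valence": -1
  },
  "bath": {
    "molarity": 1.0
  },
  "protocol": {
    "protocol": "electrical",
    "applied_mV": 50.0,
    "anode_side": "left"
  },
  "solver": {
    "dt": 2.5e-07,
    "t_end": 5e-05,
    "order": 2,
    "steady_tolerance": 10.0
  },
  "species": [
    {
      "name": "Na+",
      "valence": 1,
      "diffusivity": 1e-07
    },
    {
      "name": "Cl-",
      "valence": -1,
      "diffusivity": 1e-07
    }
  ]
}
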