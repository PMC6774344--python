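{
  "name": "paper_table1_electrical",
  "geometry": {
    "dimension": 2,
    "bath_extent": 0.015,
    "gel_shape": "square",
    "gel_extent": 0.0025,
    "refinement_band": 0.002,
    "base_resolution": 0.0005,
    "refined_resolution": 0.0001
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
    "dt": 10.0,
    "t_end": 1600.0,
    "order": 2,
    "steady_tolerance": 1e-08
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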