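{
  "comment": "Reaction-to-cofactor stoichiometry for the bundled B. methanolicus models (positive = producer, negative = consumer, per unit of net flux). detox lumps the linear formaldehyde detoxification branch: methylene-THF dehydrogenase (NADPH), formate dehydrogenase (NADH) and formate-THF ligase (ATP). PTS uptake reactions consume one ATP equivalent. Succinyl-CoA synthetase ATP is assimilated to akgdh. Biomass requirements (mmol per gDCW, multiplied by growth rate) are generic Gram-positive placeholder values and should be overridden when organism-specific measurements exist.",
  "po_nadh": 1.5,
  "po_fadh2": 1.0,
  "cofactors": {
    "NADPH": {"zwf": 1, "gnd": 1, "idh": 1, "mae": 1, "detox": 1},
    "NADH": {"pgk": 1, "pdh": 1, "akgdh": 1, "maldh": 1, "mdh": 1, "manupt": 1, "araupt1": 1, "araupt5": 1, "detox": 1},
    "FADH2": {"sdh": 1},
    "ATP": {"pgk": 1, "pyk": 1, "akgdh": 1, "out_Ac": 1, "detox": 1, "pfk": -1, "manupt": -1, "araupt1": -1, "araupt5": -1, "pyc": -1}
  },
  "biomass_requirements": {"NADPH": 13.0, "NADH": 0.0, "FADH2": 0.0, "ATP": 40.0}
}
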