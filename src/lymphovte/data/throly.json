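{
  "name": "ThroLy",
  "items": [
    {
      "name": "previous venous thromboembolic event",
      "points": 2,
      "conditions": [{"field": "prior_vte", "op": "flag"}]
    },
    {
      "name": "reduced mobility",
      "points": 1,
      "conditions": [{"field": "reduced_mobility", "op": "flag"}]
    },
    {
      "name": "obesity (body mass index >= 30 kg/m^2)",
      "points": 2,
      "conditions": [{"field": "bmi", "op": "ge", "threshold": 30}]
    },
    {
      "name": "extranodal localization",
      "points": 1,
      "conditions": [{"field": "extranodal", "op": "flag"}]
    },
    {
      "name": "mediastinal involvement",
      "points": 1,
      "conditions": [{"field": "mediastinal_involvement", "op": "flag"}]
    },
    {
      "name": "neutropenia (neutrophil count < 1.0 x 10^9/L)",
      "points": 1,
      "conditions": [{"field": "ne", "op": "lt", "threshold": 1.0}]
    },
    {
      "name": "hemoglobin < 100 g/L",
      "points": 1,
      "conditions": [{"field": "hb", "op": "lt", "threshold": 100}]
    }
  ],
  "bands": {"low_max": 1, "intermediate_max": 3}
}
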