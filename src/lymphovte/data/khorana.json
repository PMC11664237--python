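{
  "name": "Khorana",
  "items": [
    {
      "name": "cancer site: lymphoma (high-risk site)",
      "points": 1,
      "conditions": []
    },
    {
      "name": "pre-chemotherapy platelet count >= 350 x 10^9/L",
      "points": 1,
      "conditions": [{"field": "plt", "op": "ge", "threshold": 350}]
    },
    {
      "name": "hemoglobin < 100 g/L or use of erythropoiesis-stimulating agents",
      "points": 1,
      "conditions": [
        {"field": "hb", "op": "lt", "threshold": 100},
        {"field": "esa_use", "op": "flag"}
      ]
    },
    {
      "name": "pre-chemotherapy leukocyte count > 11 x 10^9/L",
      "points": 1,
      "conditions": [{"field": "wbc", "op": "gt", "threshold": 11}]
    },
    {
      "name": "body mass index >= 35 kg/m^2",
      "points": 1,
      "conditions": [{"field": "bmi", "op": "ge", "threshold": 35}]
    }
  ],
  "bands": {"low_max": 0, "intermediate_max": 2}
}
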