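{
  "species": 196,
  "reactions": 229,
  "kind_counts": {
    "biomass": 9,
    "gap_fill": 39,
    "heterologous": 1,
    "inflow": 3,
    "intracellular": 160,
    "maintenance": 1,
    "outflow": 16
  },
  "conditions": {
    "glucose_uptake": 3.92,
    "ngam": 7.6,
    "gam": 220.0,
    "target_growth": 0.042
  },
  "max_growth": 0.0420119888311192,
  "fitted_gam": 219.7265625,
  "fitted_growth": 0.04206076172910197,
  "envelope": {
    "n_points": 15,
    "growth": [
      0.0,
      0.003000856345079943,
      0.006001712690159886,
      0.009002569035239829,
      0.012003425380319772,
      0.015004281725399716,
      0.018005138070479657,
      0.0210059944155596,
      0.024006850760639544,
      0.027007707105719488,
      0.03000856345079943,
      0.033009419795879374,
      0.036010276140959314,
      0.03901113248603926,
      0.0420119888311192
    ],
    "ethanol": [
      7.6,
      7.520532376084946,
      7.037353974543696,
      6.554175573002446,
      6.070997171461197,
      5.587818769919946,
      5.104640368378701,
      4.621461966837451,
      4.138283565296198,
      3.538114285714282,
      2.8304914285714258,
      2.122868571428567,
      1.4152457142857084,
      0.7076228571428542,
      -0.0
    ]
  },
  "acetate_restriction": {
    "reference": {
      "acetate_cap": 2.0,
      "max_growth": 0.01419399095692424,
      "ethanol": 5.718286527544374
    },
    "restricted": {
      "acetate_cap": 0.6,
      "max_growth": 0.005009959733723953,
      "ethanol": 7.197039595283318
    },
    "ethanol_gain_pct": 25.860072953951295
  }
}
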