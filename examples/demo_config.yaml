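# Demonstration configuration for the synthetic projection study.
# All keys map 1:1 to heatattrib.pipeline.PipelineConfig fields;
# omitted keys keep their defaults.

# 10 x 10 half-degree grid, four latitude-band climate zones
nlat: 10
nlon: 10
lat0: 25.0
lon0: 105.0
spacing: 0.5
n_zones: 4

ref_period: [1986, 2005]
horizon: [1986, 2100]
windows:
  baseline: [1986, 2005]
  "2030": [2021, 2040]
  "2060": [2051, 2070]
  "2090": [2081, 2100]

# heatwave definition
percentile: 92.5
min_run: 3
season: [5, 9]

# warming trend per scenario, degC per decade; three ensemble members each
scenario_trends:
  low: 0.1
  mid: 0.25
  high: 0.5
n_models: 3

# fertility-variant population scenarios: [peak total, peak year, aging rate]
pop_scenarios:
  low: [4.5e7, 2028, 0.0030]
  medium: [5.0e7, 2030, 0.0025]
  high: [5.5e7, 2035, 0.0020]
central_pop: medium

mc_samples: 1000
uncertainty_param_draws: 200
seed: 1234
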