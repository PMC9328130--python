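# Default synthetic-table configuration: water drainage.
# Drainage shows essentially no treatment effect and no true heterogeneity
# (Q well below df in the compiled tables), hence ratios near 1 and tau2 = 0.
response: water_drainage
n_articles: 18
obs_per_article: [8, 20]
tau2: 0.0
sigma2_article: 0.0
baseline_ncc: {meanlog: 5.298, sdlog: 0.6}   # control drainage ~200 mm median
replicate_dist:
  - {n_cc: 1, n_ncc: 1, prob: 0.60}
  - {n_cc: 2, n_ncc: 2, prob: 0.05}
  - {n_cc: 3, n_ncc: 3, prob: 0.15}
  - {n_cc: 4, n_ncc: 4, prob: 0.15}
  - {n_cc: 3, n_ncc: 4, prob: 0.05}
covariates:
  rainfall_range: [300, 1400]
  temp_range: [4, 18]
  slope_rainfall: 0.0
  slope_temp: 0.0
subgroups:
  cc_family:
    levels:
      Poaceae: {weight: 203, mean_ratio: 0.97}
      Brassicaceae: {weight: 16, mean_ratio: 0.85}
      Leguminosae: {weight: 11, mean_ratio: 1.00}
      Multigenera: {weight: 10, mean_ratio: 0.97}
    missing_prob: 0.0
  soil_order:
    levels:
      Ultisols: {weight: 9}
      Mollisols: {weight: 152}
      Alfisols: {weight: 14}
      Inceptisols: {weight: 24}
      Entisols: {weight: 12}
    missing_prob: 0.12
  soil_texture:
    levels:
      Silty clay loam: {weight: 14}
      Clay loam: {weight: 119}
      Silt loam: {weight: 34}
      Loam: {weight: 10}
      Sandy loam: {weight: 48}
      Loamy sand: {weight: 12}
    missing_prob: 0.01
  main_crop:
    levels:
      Tomato: {weight: 10}
      Soybean: {weight: 63}
      Crop rotation: {weight: 6}
      Corn: {weight: 80}
      Barley: {weight: 22}
      Others: {weight: 8}
    missing_prob: 0.21
  tillage:
    levels:
      CT: {weight: 5}
      NT: {weight: 3}
      RT: {weight: 2}
    missing_prob: 0.30
genus_by_family:
  Poaceae: {Avena: 5, Hordeum: 18, Poa: 4, Secale: 154, Triticum: 21}
  Brassicaceae: {Brassica: 6, Raphanus: 10}
  Leguminosae: {Vicia: 10}
  Multigenera: {Multigenera: 10}
seed: 0
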