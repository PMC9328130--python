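# Default synthetic-table configuration: nitrate leaching.
# Marginal structure mirrors a 41-article compilation: level weights are the
# observation counts of the compiled moderator table, family mean ratios the
# reported family-level reductions (Brassicaceae 75%, Poaceae 52%, legumes
# ~40%, Asteraceae none, mixtures like Poaceae). Only cc_family carries
# nonzero means, so every moderator's subgroup truth is unambiguous.
response: nitrate_leaching
n_articles: 41
obs_per_article: [14, 40]
tau2: 0.3
sigma2_article: 0.0
baseline_ncc: {meanlog: 3.401, sdlog: 1.0}   # control leaching ~30 kg N/ha median
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
      Poaceae: {weight: 348, mean_ratio: 0.48}
      Brassicaceae: {weight: 132, mean_ratio: 0.25}
      Leguminosae: {weight: 46, mean_ratio: 0.60}
      Asteraceae: {weight: 10, mean_ratio: 1.00}
      Multigenera: {weight: 55, mean_ratio: 0.48}
    missing_prob: 0.0
  soil_order:
    levels:
      Ultisols: {weight: 9}
      Mollisols: {weight: 273}
      Histosols: {weight: 44}
      Alfisols: {weight: 9}
      Inceptisols: {weight: 95}
      Entisols: {weight: 46}
    missing_prob: 0.19
  soil_texture:
    levels:
      Clay: {weight: 6}
      Silty clay loam: {weight: 48}
      Clay loam: {weight: 146}
      Silt loam: {weight: 82}
      Loam: {weight: 102}
      Sandy loam: {weight: 146}
      Loamy sand: {weight: 46}
      Sandy: {weight: 12}
    missing_prob: 0.005
  main_crop:
    levels:
      Tomato: {weight: 10}
      Potato: {weight: 7}
      Broccoli: {weight: 12}
      Sugar beet: {weight: 7}
      Sunflower: {weight: 9}
      Soybean: {weight: 80}
      Corn: {weight: 139}
      Wheat: {weight: 23}
      Barley: {weight: 114}
      Other beans: {weight: 6}
      Crop rotation: {weight: 37}
    missing_prob: 0.23
  tillage:
    levels:
      CT: {weight: 5}
      NT: {weight: 3}
      RT: {weight: 2}
    missing_prob: 0.30
genus_by_family:
  Poaceae: {Avena: 19, Hordeum: 21, Lolium: 5, Poa: 6, Secale: 277, Triticum: 20}
  Brassicaceae: {Brassica: 84, Camelina: 12, Raphanus: 24, Thlaspi: 12}
  Leguminosae: {Trifolium: 7, Vicia: 39}
  Asteraceae: {Helianthus: 10}
  Multigenera: {Multigenera: 55}
seed: 0
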