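# Synthetic scenario: 21 odontocete species stranded around Aotearoa New
# Zealand, 2010-2021.  Per-species bivariate-normal parameters are the
# published community's Suess-corrected means +/- 1 SD and sample sizes.
# Species observed only once have no published SD; a nominal within-species
# SD of 0.5 permil is assumed for both isotopes (it only shapes the single
# draw's jitter, and such species never enter comparative statistics).
defaults:
  year_range: [2010, 2021]

species:
  - {species: "Bottlenose dolphin", latin_name: "Tursiops truncatus", habitat_group: neritic,
     n: 10, mean_d13C: -16.99, sd_d13C: 0.50, mean_d15N: 14.83, sd_d15N: 0.81}
  - {species: "Hector's dolphin", latin_name: "Cephalorhyncus hectori hectori", habitat_group: neritic,
     n: 10, mean_d13C: -16.91, sd_d13C: 0.63, mean_d15N: 15.26, sd_d15N: 0.70}
  - {species: "Common dolphin", latin_name: "Delphinus delphis", habitat_group: mesopelagic,
     n: 18, mean_d13C: -17.45, sd_d13C: 0.72, mean_d15N: 14.11, sd_d15N: 1.31}
  - {species: "Dusky dolphin", latin_name: "Lagenorhynchus obscurus", habitat_group: mesopelagic,
     n: 13, mean_d13C: -17.48, sd_d13C: 0.48, mean_d15N: 12.84, sd_d15N: 1.34}
  - {species: "False killer whale", latin_name: "Pseudorca crassidens", habitat_group: mesopelagic,
     n: 2, mean_d13C: -18.20, sd_d13C: 1.46, mean_d15N: 13.82, sd_d15N: 0.17}
  - {species: "Killer whale", latin_name: "Orcinus orca", habitat_group: mesopelagic,
     n: 15, mean_d13C: -16.75, sd_d13C: 0.31, mean_d15N: 15.43, sd_d15N: 0.49}
  - {species: "Long-finned pilot whale", latin_name: "Globicephala melas edwardii", habitat_group: mesopelagic,
     n: 22, mean_d13C: -17.45, sd_d13C: 0.71, mean_d15N: 12.84, sd_d15N: 1.04}
  - {species: "Pygmy killer whale", latin_name: "Feresa attenuata", habitat_group: mesopelagic,
     n: 3, mean_d13C: -17.19, sd_d13C: 0.35, mean_d15N: 14.50, sd_d15N: 0.08}
  - {species: "Pygmy sperm whale", latin_name: "Kogia breviceps", habitat_group: mesopelagic,
     n: 10, mean_d13C: -17.59, sd_d13C: 0.49, mean_d15N: 14.14, sd_d15N: 0.46}
  - {species: "Risso's dolphin", latin_name: "Grampus griseus", habitat_group: mesopelagic,
     n: 4, mean_d13C: -18.32, sd_d13C: 1.90, mean_d15N: 13.80, sd_d15N: 1.15}
  - {species: "Short-finned pilot whale", latin_name: "Globicephala macrorhynchus", habitat_group: mesopelagic,
     n: 4, mean_d13C: -16.80, sd_d13C: 0.11, mean_d15N: 13.62, sd_d15N: 0.85}
  - {species: "Striped dolphin", latin_name: "Stenella coeruleoalba", habitat_group: mesopelagic,
     n: 10, mean_d13C: -17.74, sd_d13C: 0.49, mean_d15N: 12.88, sd_d15N: 0.51}
  - {species: "Arnoux's beaked whale", latin_name: "Berardius arnuxii", habitat_group: bathypelagic,
     n: 1, mean_d13C: -27.16, sd_d13C: 0.5, mean_d15N: 9.63, sd_d15N: 0.5}
  - {species: "Cuvier's beaked whale", latin_name: "Ziphius cavirostris", habitat_group: bathypelagic,
     n: 3, mean_d13C: -17.74, sd_d13C: 0.26, mean_d15N: 13.64, sd_d15N: 1.54}
  - {species: "Gray's beaked whale", latin_name: "Mesoplodon grayi", habitat_group: bathypelagic,
     n: 11, mean_d13C: -17.95, sd_d13C: 0.65, mean_d15N: 13.03, sd_d15N: 0.86}
  - {species: "Southern bottlenose whale", latin_name: "Hyperoodon planifrons", habitat_group: bathypelagic,
     n: 1, mean_d13C: -17.34, sd_d13C: 0.5, mean_d15N: 13.69, sd_d15N: 0.5}
  - {species: "Sperm whale", latin_name: "Physeter macrocephalus", habitat_group: bathypelagic,
     n: 16, mean_d13C: -17.24, sd_d13C: 0.50, mean_d15N: 14.54, sd_d15N: 0.62}
  - {species: "Strap-toothed whale", latin_name: "Mesoplodon layardii", habitat_group: bathypelagic,
     n: 2, mean_d13C: -23.03, sd_d13C: 0.16, mean_d15N: 11.42, sd_d15N: 0.17}
  - {species: "Hourglass dolphin", latin_name: "Lagenorhynchus cruciger", habitat_group: polar,
     n: 2, mean_d13C: -19.27, sd_d13C: 0.05, mean_d15N: 8.85, sd_d15N: 0.18}
  - {species: "Southern right whale dolphin", latin_name: "Lissodelphis peronii", habitat_group: polar,
     n: 2, mean_d13C: -20.06, sd_d13C: 0.22, mean_d15N: 10.78, sd_d15N: 0.66}
  - {species: "Spectacled porpoise", latin_name: "Phocoena dioptrica", habitat_group: polar,
     n: 5, mean_d13C: -19.17, sd_d13C: 0.65, mean_d15N: 9.51, sd_d15N: 0.61}
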