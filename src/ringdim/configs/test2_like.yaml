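# Low-contrast plasma study: 18 unpaired individuals in two diet groups with
# a weak planted group effect, no outliers, no dilution variation (plasma is
# tightly regulated), rendered through 4 NMR-like and 8 LC-MS-like profiles.
# A few dominant metabotype directions carry most of the biological variance
# so the group contrast is buried below the inter-individual structure.
seed: 2015
simulate:
  design:
    n_individuals: 18
    contrast: low
    paired_spike: false
    n_outliers: 0
    dilution_cv: 0.0
    sg_reference: 1.020
  platforms:
    - {instrument_id: N1, technology: NMR, ion_mode: none, n_features: 881,
       variance_shares: {group: 0.07, metabotype_01: 0.30, metabotype_02: 0.17,
                         metabotype: 0.16},
       noise_fraction: 0.30}
    - {instrument_id: N3, technology: NMR, ion_mode: none, n_features: 300,
       variance_shares: {group: 0.07, metabotype_01: 0.28, metabotype_02: 0.18,
                         metabotype: 0.15},
       noise_fraction: 0.32}
    - {instrument_id: N4, technology: NMR, ion_mode: none, n_features: 9550,
       variance_shares: {group: 0.06, metabotype_01: 0.27, metabotype_02: 0.16,
                         metabotype: 0.16},
       noise_fraction: 0.35}
    - {instrument_id: N5, technology: NMR, ion_mode: none, n_features: 120,
       variance_shares: {group: 0.07, metabotype_01: 0.29, metabotype_02: 0.17,
                         metabotype: 0.15},
       noise_fraction: 0.32}
    - {instrument_id: O1P, technology: LCMS, ion_mode: pos, n_features: 710,
       variance_shares: {group: 0.04, metabotype_01: 0.20, metabotype_02: 0.12,
                         metabotype: 0.10},
       noise_fraction: 0.54}
    - {instrument_id: O2P, technology: LCMS, ion_mode: pos, n_features: 1295,
       variance_shares: {group: 0.04, metabotype_01: 0.22, metabotype_02: 0.12,
                         metabotype: 0.10},
       noise_fraction: 0.52}
    - {instrument_id: O3P, technology: LCMS, ion_mode: pos, n_features: 1979,
       variance_shares: {group: 0.03, metabotype_01: 0.14, metabotype_02: 0.08,
                         metabotype: 0.08},
       noise_fraction: 0.67}
    - {instrument_id: O3N, technology: LCMS, ion_mode: neg, n_features: 795,
       variance_shares: {group: 0.04, metabotype_01: 0.19, metabotype_02: 0.11,
                         metabotype: 0.10},
       noise_fraction: 0.56}
    - {instrument_id: Q1P, technology: LCMS, ion_mode: pos, n_features: 504,
       variance_shares: {group: 0.04, metabotype_01: 0.22, metabotype_02: 0.12,
                         metabotype: 0.10},
       noise_fraction: 0.52}
    - {instrument_id: Q3P, technology: LCMS, ion_mode: pos, n_features: 2631,
       variance_shares: {group: 0.04, metabotype_01: 0.20, metabotype_02: 0.12,
                         metabotype: 0.10},
       noise_fraction: 0.54}
    - {instrument_id: Q4P, technology: LCMS, ion_mode: pos, n_features: 2277,
       variance_shares: {group: 0.04, metabotype_01: 0.20, metabotype_02: 0.12,
                         metabotype: 0.10},
       noise_fraction: 0.54}
    - {instrument_id: Q5P, technology: LCMS, ion_mode: pos, n_features: 1595,
       variance_shares: {group: 0.04, metabotype_01: 0.19, metabotype_02: 0.11,
                         metabotype: 0.10},
       noise_fraction: 0.56}
preprocess:
  normalize: none
  scale: unit_block_variance
rv:
  variant: classic
  permutations: 199
ccswa:
  n_components: 4
selection:
  component: auto
  rule: auto
network:
  cutoff: auto
  allowed_isolated: 1
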