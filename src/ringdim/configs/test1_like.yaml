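# High-contrast urine spiking study: 14 paired individuals (native + spiked),
# one blind and one unexpected outlier individual, urine-dilution variation,
# rendered through 5 NMR-like and 9 LC-MS-like platform profiles whose
# feature counts span two orders of magnitude.
seed: 2014
simulate:
  design:
    n_individuals: 14
    contrast: high
    paired_spike: true
    n_outliers: 2
    dilution_cv: 0.25
    sg_reference: 1.020
  platforms:
    - {instrument_id: N1, technology: NMR, ion_mode: none, n_features: 751,
       variance_shares: {group: 0.70, metabotype: 0.10, outlier: 0.06},
       noise_fraction: 0.14, responds_to_spike: 0.25}
    - {instrument_id: N2, technology: NMR, ion_mode: none, n_features: 252,
       variance_shares: {group: 0.35, metabotype: 0.38, outlier: 0.08},
       noise_fraction: 0.19, responds_to_spike: 0.25}
    - {instrument_id: N3, technology: NMR, ion_mode: none, n_features: 889,
       variance_shares: {group: 0.72, metabotype: 0.09, outlier: 0.05},
       noise_fraction: 0.14, responds_to_spike: 0.25}
    - {instrument_id: N4, technology: NMR, ion_mode: none, n_features: 9699,
       variance_shares: {group: 0.68, metabotype: 0.11, outlier: 0.05},
       noise_fraction: 0.16, responds_to_spike: 0.25}
    - {instrument_id: N5, technology: NMR, ion_mode: none, n_features: 233,
       variance_shares: {group: 0.70, metabotype: 0.10, outlier: 0.06},
       noise_fraction: 0.14, responds_to_spike: 0.25}
    - {instrument_id: O1P, technology: LCMS, ion_mode: pos, n_features: 5035,
       variance_shares: {group: 0.30, metabotype: 0.28, outlier: 0.10},
       noise_fraction: 0.32, responds_to_spike: 0.12}
    - {instrument_id: Q6P, technology: LCMS, ion_mode: pos, n_features: 1922,
       variance_shares: {group: 0.25, metabotype: 0.25, outlier: 0.08},
       noise_fraction: 0.42, responds_to_spike: 0.12}
    - {instrument_id: Q6N, technology: LCMS, ion_mode: neg, n_features: 314,
       variance_shares: {group: 0.22, metabotype: 0.24, outlier: 0.08},
       noise_fraction: 0.46, responds_to_spike: 0.12}
    - {instrument_id: O3P, technology: LCMS, ion_mode: pos, n_features: 1827,
       variance_shares: {group: 0.35, metabotype: 0.30, outlier: 0.10},
       noise_fraction: 0.25, responds_to_spike: 0.12}
    - {instrument_id: O3N, technology: LCMS, ion_mode: neg, n_features: 1715,
       variance_shares: {group: 0.32, metabotype: 0.28, outlier: 0.10},
       noise_fraction: 0.30, responds_to_spike: 0.12}
    - {instrument_id: O4P, technology: LCMS, ion_mode: pos, n_features: 2668,
       variance_shares: {group: 0.34, metabotype: 0.30, outlier: 0.10},
       noise_fraction: 0.26, responds_to_spike: 0.12}
    - {instrument_id: Q1P, technology: LCMS, ion_mode: pos, n_features: 1181,
       variance_shares: {group: 0.30, metabotype: 0.28, outlier: 0.10},
       noise_fraction: 0.32, responds_to_spike: 0.12}
    - {instrument_id: Q1N, technology: LCMS, ion_mode: neg, n_features: 1288,
       variance_shares: {group: 0.28, metabotype: 0.27, outlier: 0.10},
       noise_fraction: 0.35, responds_to_spike: 0.12}
    - {instrument_id: Q3P, technology: LCMS, ion_mode: pos, n_features: 908,
       variance_shares: {group: 0.30, metabotype: 0.26, outlier: 0.09},
       noise_fraction: 0.35, responds_to_spike: 0.12}
preprocess:
  normalize: sg
  sg_reference: 1.020
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
  allowed_isolated: 0
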