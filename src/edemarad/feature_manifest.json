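{
 "version": 1,
 "n_features": 253,
 "names": [
  "sem_age",
  "sem_menopause",
  "sem_family_history",
  "sem_hormone_therapy",
  "sem_location",
  "sem_stadiation",
  "sem_margins",
  "sem_dimensions",
  "sem_morphology",
  "sem_kinetic_curve",
  "sem_edema_type",
  "fo_mean",
  "fo_sd",
  "fo_skewness",
  "fo_kurtosis",
  "fo_energy",
  "fo_entropy",
  "fo_max",
  "fo_max_position",
  "fo_max_energy",
  "fo_range",
  "fo_n_rel_max",
  "fo_rel_max_energy",
  "lbp_basic_mean",
  "lbp_basic_sd",
  "lbp_basic_skewness",
  "lbp_basic_kurtosis",
  "lbp_basic_energy",
  "lbp_basic_entropy",
  "lbp_basic_max",
  "lbp_basic_max_position",
  "lbp_basic_max_energy",
  "lbp_basic_range",
  "lbp_basic_n_rel_max",
  "lbp_basic_rel_max_energy",
  "lbp_ri_mean",
  "lbp_ri_sd",
  "lbp_ri_skewness",
  "lbp_ri_kurtosis",
  "lbp_ri_energy",
  "lbp_ri_entropy",
  "lbp_ri_max",
  "lbp_ri_max_position",
  "lbp_ri_max_energy",
  "lbp_ri_range",
  "lbp_ri_n_rel_max",
  "lbp_ri_rel_max_energy",
  "lbp_u2_mean",
  "lbp_u2_sd",
  "lbp_u2_skewness",
  "lbp_u2_kurtosis",
  "lbp_u2_energy",
  "lbp_u2_entropy",
  "lbp_u2_max",
  "lbp_u2_max_position",
  "lbp_u2_max_energy",
  "lbp_u2_range",
  "lbp_u2_n_rel_max",
  "lbp_u2_rel_max_energy",
  "lbp_riu2_mean",
  "lbp_riu2_sd",
  "lbp_riu2_skewness",
  "lbp_riu2_kurtosis",
  "lbp_riu2_energy",
  "lbp_riu2_entropy",
  "lbp_riu2_max",
  "lbp_riu2_max_position",
  "lbp_riu2_max_energy",
  "lbp_riu2_range",
  "lbp_riu2_n_rel_max",
  "lbp_riu2_rel_max_energy",
  "glcm_00_autocorr",
  "glcm_00_covariance",
  "glcm_00_inertia",
  "glcm_00_abs_inertia",
  "glcm_00_inv_inertia",
  "glcm_00_energy",
  "glcm_00_entropy",
  "glcm_01_autocorr",
  "glcm_01_covariance",
  "glcm_01_inertia",
  "glcm_01_abs_inertia",
  "glcm_01_inv_inertia",
  "glcm_01_energy",
  "glcm_01_entropy",
  "glcm_02_autocorr",
  "glcm_02_covariance",
  "glcm_02_inertia",
  "glcm_02_abs_inertia",
  "glcm_02_inv_inertia",
  "glcm_02_energy",
  "glcm_02_entropy",
  "glcm_03_autocorr",
  "glcm_03_covariance",
  "glcm_03_inertia",
  "glcm_03_abs_inertia",
  "glcm_03_inv_inertia",
  "glcm_03_energy",
  "glcm_03_entropy",
  "glcm_04_autocorr",
  "glcm_04_covariance",
  "glcm_04_inertia",
  "glcm_04_abs_inertia",
  "glcm_04_inv_inertia",
  "glcm_04_energy",
  "glcm_04_entropy",
  "glcm_05_autocorr",
  "glcm_05_covariance",
  "glcm_05_inertia",
  "glcm_05_abs_inertia",
  "glcm_05_inv_inertia",
  "glcm_05_energy",
  "glcm_05_entropy",
  "glcm_06_autocorr",
  "glcm_06_covariance",
  "glcm_06_inertia",
  "glcm_06_abs_inertia",
  "glcm_06_inv_inertia",
  "glcm_06_energy",
  "glcm_06_entropy",
  "glcm_07_autocorr",
  "glcm_07_covariance",
  "glcm_07_inertia",
  "glcm_07_abs_inertia",
  "glcm_07_inv_inertia",
  "glcm_07_energy",
  "glcm_07_entropy",
  "glcm_08_autocorr",
  "glcm_08_covariance",
  "glcm_08_inertia",
  "glcm_08_abs_inertia",
  "glcm_08_inv_inertia",
  "glcm_08_energy",
  "glcm_08_entropy",
  "glcm_09_autocorr",
  "glcm_09_covariance",
  "glcm_09_inertia",
  "glcm_09_abs_inertia",
  "glcm_09_inv_inertia",
  "glcm_09_energy",
  "glcm_09_entropy",
  "glcm_10_autocorr",
  "glcm_10_covariance",
  "glcm_10_inertia",
  "glcm_10_abs_inertia",
  "glcm_10_inv_inertia",
  "glcm_10_energy",
  "glcm_10_entropy",
  "glcm_11_autocorr",
  "glcm_11_covariance",
  "glcm_11_inertia",
  "glcm_11_abs_inertia",
  "glcm_11_inv_inertia",
  "glcm_11_energy",
  "glcm_11_entropy",
  "glcm_12_autocorr",
  "glcm_12_covariance",
  "glcm_12_inertia",
  "glcm_12_abs_inertia",
  "glcm_12_inv_inertia",
  "glcm_12_energy",
  "glcm_12_entropy",
  "glcm_13_autocorr",
  "glcm_13_covariance",
  "glcm_13_inertia",
  "glcm_13_abs_inertia",
  "glcm_13_inv_inertia",
  "glcm_13_energy",
  "glcm_13_entropy",
  "glcm_14_autocorr",
  "glcm_14_covariance",
  "glcm_14_inertia",
  "glcm_14_abs_inertia",
  "glcm_14_inv_inertia",
  "glcm_14_energy",
  "glcm_14_entropy",
  "glcm_15_autocorr",
  "glcm_15_covariance",
  "glcm_15_inertia",
  "glcm_15_abs_inertia",
  "glcm_15_inv_inertia",
  "glcm_15_energy",
  "glcm_15_entropy",
  "glcm_16_autocorr",
  "glcm_16_covariance",
  "glcm_16_inertia",
  "glcm_16_abs_inertia",
  "glcm_16_inv_inertia",
  "glcm_16_energy",
  "glcm_16_entropy",
  "glcm_17_autocorr",
  "glcm_17_covariance",
  "glcm_17_inertia",
  "glcm_17_abs_inertia",
  "glcm_17_inv_inertia",
  "glcm_17_energy",
  "glcm_17_entropy",
  "glcm_18_autocorr",
  "glcm_18_covariance",
  "glcm_18_inertia",
  "glcm_18_abs_inertia",
  "glcm_18_inv_inertia",
  "glcm_18_energy",
  "glcm_18_entropy",
  "glcm_19_autocorr",
  "glcm_19_covariance",
  "glcm_19_inertia",
  "glcm_19_abs_inertia",
  "glcm_19_inv_inertia",
  "glcm_19_energy",
  "glcm_19_entropy",
  "glcm_20_autocorr",
  "glcm_20_covariance",
  "glcm_20_inertia",
  "glcm_20_abs_inertia",
  "glcm_20_inv_inertia",
  "glcm_20_energy",
  "glcm_20_entropy",
  "glcm_21_autocorr",
  "glcm_21_covariance",
  "glcm_21_inertia",
  "glcm_21_abs_inertia",
  "glcm_21_inv_inertia",
  "glcm_21_energy",
  "glcm_21_entropy",
  "glcm_22_autocorr",
  "glcm_22_covariance",
  "glcm_22_inertia",
  "glcm_22_abs_inertia",
  "glcm_22_inv_inertia",
  "glcm_22_energy",
  "glcm_22_entropy",
  "glcm_23_autocorr",
  "glcm_23_covariance",
  "glcm_23_inertia",
  "glcm_23_abs_inertia",
  "glcm_23_inv_inertia",
  "glcm_23_energy",
  "glcm_23_entropy",
  "glcm_24_autocorr",
  "glcm_24_covariance",
  "glcm_24_inertia",
  "glcm_24_abs_inertia",
  "glcm_24_inv_inertia",
  "glcm_24_energy",
  "glcm_24_entropy",
  "glcm_25_autocorr",
  "glcm_25_covariance",
  "glcm_25_inertia",
  "glcm_25_abs_inertia",
  "glcm_25_inv_inertia",
  "glcm_25_energy",
  "glcm_25_entropy"
 ],
 "blocks": {
  "semantic": 11,
  "first_order": 12,
  "lbp_top": 48,
  "glcm": 182
 }
}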