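{
  "conformers": {
    "extended_fraction": 0.1347,
    "folded_fraction": 0.8346,
    "unassigned_fraction": 0.0307
  },
  "diffusion": {
    "fitted_D_1e-7_cm2_s": 3.9169641,
    "fitted_D_se_1e-7_cm2_s": 1.1762826,
    "true_D_1e-7_cm2_s": 3.9
  },
  "membrane": {
    "area_per_lipid_nm2": 0.60822509,
    "area_se_nm2": 0.00029981735,
    "thickness_nm": 4.0003571,
    "thickness_se_nm": 0.00021073294
  },
  "pair_structure": {
    "first_barrier_kJ_mol": 5.9219273,
    "first_shell_nm": 0.775,
    "kT_kJ_mol": 2.6868186
  },
  "residence": {
    "mean_lifetime_ps": 200.0,
    "n_episodes": 1,
    "occupancy": 1.0
  },
  "seed": 1,
  "version": "0.1.0",
  "wtm": {
    "fes_basin_error_kJ_mol": 1.1627684,
    "first_barrier_kJ_mol": 15.176909,
    "first_hill_kJ_mol": 1.0,
    "n_basins": 3,
    "n_hills": 2000,
    "true_barrier_kJ_mol": 15.0
  }
}
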