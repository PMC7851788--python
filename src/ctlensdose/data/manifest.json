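{
  "al_mass_attenuation.csv": {
    "quantity": "mass attenuation coefficient mu/rho",
    "material": "aluminum",
    "units": "cm^2/g",
    "interpolation": "log-log",
    "source": "Hubbell & Seltzer, NIST standard reference tables of X-ray mass attenuation coefficients (elemental Al)"
  },
  "al_mass_energy_absorption.csv": {
    "quantity": "mass energy-absorption coefficient mu_en/rho",
    "material": "aluminum",
    "units": "cm^2/g",
    "interpolation": "log-log",
    "source": "Hubbell & Seltzer, NIST standard reference tables (elemental Al)"
  },
  "air_mass_attenuation.csv": {
    "quantity": "mass attenuation coefficient mu/rho",
    "material": "dry air, near sea level",
    "units": "cm^2/g",
    "interpolation": "log-log",
    "source": "Hubbell & Seltzer, NIST standard reference tables (dry air)"
  },
  "air_mass_energy_absorption.csv": {
    "quantity": "mass energy-absorption coefficient mu_en/rho",
    "material": "dry air, near sea level",
    "units": "cm^2/g",
    "interpolation": "log-log",
    "source": "Hubbell & Seltzer, NIST standard reference tables (dry air)"
  },
  "hp3_ka_cylinder0_synthetic.csv": {
    "quantity": "Hp(3)/Ka personal dose equivalent conversion coefficient",
    "material": "ICRU tissue, cylinder head phantom, photons at 0 degrees incidence",
    "units": "Sv/Gy",
    "interpolation": "linear",
    "source": "synthetic reconstruction of a Behrens-type cylinder-phantom tabulation (ISO 4037-3:2019 geometry); smooth peaked curve anchored to K = 1.650 at 56.47 keV"
  },
  "w_mass_attenuation_approx.csv": {
    "quantity": "mass attenuation coefficient mu/rho (approximate, K-edge at 69.525 keV)",
    "material": "tungsten",
    "units": "cm^2/g",
    "interpolation": "log-log",
    "source": "approximate values after standard elemental compilations; used only to shape anode self-filtration inside the spectrum model"
  },
  "densities_g_cm3": {"Al": 2.699, "air": 0.001205, "W": 19.3}
}
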