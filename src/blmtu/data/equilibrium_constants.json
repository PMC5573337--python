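{
  "comment": "Thermodynamic formation constants (log10, 25 C, infinite dilution, activity basis). 'reaction' documents the formation reaction; 'source' records provenance. M-HCO3+ constants are poorly constrained in the literature (spread > 2 log units); the CuHCO3+ value is the legacy MINTEQ/WHAM-era constant (logK 14.62 for Cu2+ + H+ + CO3 2- = CuHCO3+, i.e. 4.29 versus HCO3-), chosen because this module emulates a WHAM 6.0 calculation; the modern IUPAC-recommended value is ~1.8. CoHCO3+ uses a NIST/Smith-Martell-range value.",
  "carbonate_system": {
    "logK_H_CO2": {"value": -1.47, "reaction": "CO2(g) = CO2(aq)", "units": "mol/L/atm", "source": "Henry's law constant, Stumm & Morgan"},
    "logKa1": {"value": -6.35, "reaction": "CO2(aq) + H2O = H+ + HCO3-", "source": "NIST 46 / Stumm & Morgan"},
    "logKa2": {"value": -10.33, "reaction": "HCO3- = H+ + CO3-2", "source": "NIST 46 / Stumm & Morgan"},
    "logKw": {"value": -14.0, "reaction": "H2O = H+ + OH-", "source": "NIST"}
  },
  "complexes": {
    "CuOH+":     {"metal": "Cu", "ligand": "OH-",   "logK": 6.30, "charge": 1, "source": "Baes & Mesmer hydrolysis (*K1 = -7.7)"},
    "CuCO3(aq)": {"metal": "Cu", "ligand": "CO3-2", "logK": 6.75, "charge": 0, "source": "NIST 46"},
    "CuHCO3+":   {"metal": "Cu", "ligand": "HCO3-", "logK": 4.29, "charge": 1, "source": "legacy MINTEQ/WHAM-era (14.62 - 10.33); see file comment"},
    "CoOH+":     {"metal": "Co", "ligand": "OH-",   "logK": 4.30, "charge": 1, "source": "Baes & Mesmer hydrolysis (*K1 = -9.7)"},
    "CoCO3(aq)": {"metal": "Co", "ligand": "CO3-2", "logK": 4.23, "charge": 0, "source": "MINTEQ database"},
    "CoHCO3+":   {"metal": "Co", "ligand": "HCO3-", "logK": 2.20, "charge": 1, "source": "NIST/Smith & Martell range"}
  },
  "ion_pairs": {
    "MgSO4(aq)": {"metal": "Mg", "ligand": "SO4-2", "logK": 2.37, "charge": 0, "source": "NIST 46"},
    "CaSO4(aq)": {"metal": "Ca", "ligand": "SO4-2", "logK": 2.30, "charge": 0, "source": "NIST 46"},
    "CuSO4(aq)": {"metal": "Cu", "ligand": "SO4-2", "logK": 2.36, "charge": 0, "source": "NIST 46"},
    "CoSO4(aq)": {"metal": "Co", "ligand": "SO4-2", "logK": 2.36, "charge": 0, "source": "NIST 46"}
  },
  "davies": {"A": 0.51, "b": 0.3}
}
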