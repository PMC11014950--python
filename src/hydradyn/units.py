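"""Internal unit conventions and physical constants.

All coordinates are in Å, times in ps, temperatures in K, energies in
μeV (neutron) or kJ/mol (activation), masses in Da.  Every conversion
used anywhere in the package lives here.
"""

#: ħ in μeV·ps — converts between energy (μeV) and time (ps) domains.
HBAR_UEV_PS: float = 658.2119569

#: Gas constant in kJ mol⁻¹ K⁻¹ (Arrhenius fits report E_a in kJ/mol).
R_KJ_PER_MOL_K: float = 8.314462618e-3

#: Gas constant in J mol⁻¹ K⁻¹.
R_J_PER_MOL_K: float = 8.314462618

#: Molar mass of D₂O in g/mol.  Hydration levels h (g water per g
#: protein) refer to D₂O by definition even when the underlying water
#: model is H₂O.
D2O_MOLAR_MASS: float = 20.028

#: Molar mass of H₂O in g/mol.
H2O_MOLAR_MASS: float = 18.015

#: Å per nm (radial profiles are reported in nm).
ANGSTROM_PER_NM: float = 10.0

#: Gaussian FWHM → standard deviation.
FWHM_TO_SIGMA: float = 1.0 / 2.3548200450309493  # 1/(2*sqrt(2*ln 2))
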