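# Brain tissue constitutive parameters (version 1).
# Volumetric response shared by both tissues; isochoric response is a Gent
# matrix, plus an exponential fiber-reinforcement term for white matter only
# (k1/k2 absent => isotropic).  k2 is tabulated in kPa in the source
# literature but enters the model as a dimensionless exponent coefficient.
version: 1
materials:
  white_matter:
    rho_o_kg_m3: 1140
    K_o_GPa: 2.19
    Lambda_o: 6.15
    mu_m_kPa: 550
    j_m: 1.1
    k1_kPa: 2.14
    k2_kPa: 0
  gray_matter:
    rho_o_kg_m3: 1140
    K_o_GPa: 2.19
    Lambda_o: 6.15
    mu_m_kPa: 450
    j_m: 1.4
    k1_kPa: null
    k2_kPa: null
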