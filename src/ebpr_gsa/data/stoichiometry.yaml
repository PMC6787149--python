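# Stoichiometric constants of the PAO metabolic model, one entry per named
# coefficient. The model structure (10 components x 10 processes, carbon and
# phosphorus closure, pH-linear yield laws, sequential maintenance) is enforced
# in code; this file carries the numeric conventions of the Smolders (acetate),
# Oehmen (propionate), Zeng (PHA split) and Filipe (pH) model family.
# All carbon on a C-mol basis, phosphorus on a P-mol basis, energy in mol ATP.

anaerobic:
  # glycogen demand per C-mol VFA taken up (glycolysis supplying ATP + NADH2)
  y_gly_hac: 0.50          # C-mol Gly / C-mol HAc, pH-independent
  y_gly_hpr_ref: 0.33      # C-mol Gly / C-mol HPr at pH 7
  y_gly_hpr_slope: 0.05    # d(y_gly_hpr)/d(pH)
  # CO2 evolved per C-mol VFA (PHA yield closes the carbon balance)
  co2_hac: 0.17
  co2_hpr: 0.11
  # PHA constituent split of newly formed PHA, per carbon source
  split_hac: [0.90, 0.10, 0.00]    # PHB, PHV, PH2MV
  split_hpr: [0.05, 0.55, 0.40]
  # ATP demand per C-mol VFA (transport + activation), linear in pH:
  # alpha(pH) = alpha_ref + alpha_slope * (pH - 7)
  alpha_ref: 0.75
  alpha_slope: 0.36
  # kinetic pH inhibition of VFA uptake (transport against a steeper
  # gradient at high pH): rate factor 1 - ph_kin_slope * (pH - 7)
  ph_kin_slope: 0.40
  # substrate-level ATP per C-mol glycogen run through anaerobic glycolysis
  a_gly: 0.50
  # PHB formed per C-mol glycogen consumed for maintenance ATP
  y_phb_maint: 0.75

aerobic:
  nadh_per_pha: 2.25       # mol NADH2 per C-mol PHA fully oxidized
  o2_per_pha: 1.125        # mol O2 per C-mol PHA fully oxidized
  gly_ox_atp_sub: 0.50     # substrate-level ATP per C-mol glycogen oxidized
  gly_ox_nadh: 2.0         # mol NADH2 per C-mol glycogen oxidized
  o2_per_gly: 1.0          # mol O2 per C-mol glycogen oxidized
  e_gly: 0.50              # ATP per C-mol glycogen formed from PHA
  pp_atp_base: 1.0         # ATP per P-mol poly-P polymerized (epsilon adds transport)

environment:
  k_la: 10.0               # 1/h, aeration mass-transfer coefficient
  o2_sat: 0.25             # mmol O2/l, saturation concentration
  k_switch: 1.0e-4         # smooth sequential-maintenance switching constant
  t_ref: 20.0              # degC, Arrhenius reference temperature
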