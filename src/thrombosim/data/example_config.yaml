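# Baseline crevice-channel scenario (desk-scale surrogate).
#
# Parameter provenance:
#   published model constants : mu_f 3.5e-3 Pa s, rho_f0 1060 kg/m^3,
#       C2 2e9 kg/(m^3 s), Sc 0.9, tau_sc 1.5 Pa (15 dyne/cm^2),
#       chi 30 (applied to k_ra, k_aa, k_rpd_b, k_apd_b only; reported
#       times scaled by the same factor),
#       inlet RP 3.0e14 PLT/m^3, AP = 0.01 RP, PT 1.1e-6, AT 2.844e-6,
#       heparin baseline 0.1 nmol/m^3 (bolus scenario: 0.3)
#   classical activation-network forms : agonist-weighted threshold with
#       activation time t_act, per-platelet release/synthesis rates,
#       first-order agonist inhibition, template-model thrombin inhibition
#   desk-scale calibration choices (all overridable):
#       red-cell-augmented effective diffusivities (~1e-9 m^2/s),
#       reaction-limited deposition constants (package defaults),
#       tau_sc_b 0.15 Pa, crit_T 18 U/m^3, Griffith constants first-order
#       in thrombin, and the packing overrides below (phi_crit 0.4,
#       effective deposited-platelet volume 1.1e-16 m^3)

geometry:
  preset: crevice_channel
  channel_h: 1.0e-3      # m
  crevice_w: 1.0e-3      # m
  crevice_d: 2.5e-4      # m
  length: 4.0e-3         # m
  n_across: 16           # cells across channel_h

u_inlet: 0.015           # m/s, uniform inlet profile
heparin: 0.1             # nmol/m^3
chi: 30.0                # reaction-rate and reported-time scaling
duration: 150.0          # simulated seconds (reported: chi * duration)
output_every: 5.0        # simulated seconds between CSV rows

# inlet concentrations: RP, AP, ADP, TxA2, PT, T, AT
inlet: [3.0e14, 3.0e12, 0.0, 0.0, 1.1e-6, 0.0, 2.844e-6]

flow_overrides: {}       # e.g. mu_f, rho_f0, C2
kinetics_overrides: {}   # e.g. crit_T, k_cat, t_act
transport_overrides:     # desk-scale packing calibration (see ledger)
  phi_crit: 0.4
  V_p: 1.1e-16

outdir: null             # set to write CSV series + manifest (+ VTK)
write_vtk: false
label: baseline
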