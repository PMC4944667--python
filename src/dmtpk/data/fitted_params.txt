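# Fitted pharmacokinetic parameters for the two-compartment model with
# enzymatic (Michaelis-Menten) clearance, naive-averaged intravenous DMT
# fumarate concentration data, one row per dose group, printed values verbatim.
# k12 = Q12/Vc; k21 = Q12/Vp.

[dose_0.4_mg_per_kg]
Vc_L = 0.093
Vp_L = 0.34
Km = 21.48
Km_unit = mg/L
Vm_mg_per_min = 2.00
Q12_L_per_min = 0.056

[dose_0.2_mg_per_kg]
Vc_L = 0.14
Vp_L = 0.23
Km = 9.52
Km_unit = mg/L
Vm_mg_per_min = 1.07
Q12_L_per_min = 0.046
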