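# Embryonic cell-cycle oscillator (Cdk1 / Plx1 / APC), concentrations in nM, time in min.
# Cdk1 module: cyclin synthesis feeds active Cdk1-cyclin; Cdc25 (activating) and
# Wee1 (inactivating) Hill feedbacks on Cdk1a; APC-driven degradation of both forms.
k_synth = 1.5
a_cdc25 = 0.16
b_cdc25 = 0.8
ec50_cdc25 = 35.0
n_cdc25 = 11.0
a_wee1 = 0.08
b_wee1 = 0.4
ec50_wee1 = 30.0
n_wee1 = 3.5
k_deg_basal = 0.0
k_dest = 0.1
r = 0.5
# Plx1 activation by Cdk1a, APC activation by Plx1 (fractions of totals)
k_plx_on = 1.5
k_plx_off = 0.125
ec50_plx = 68.0
n_plx = 5.0
plxtot = 1.0
k_apc_on = 1.5
k_apc_off = 0.15
ec50_apc = 0.5
n_apc = 4.0
apctot = 1.0
# basal APC activation in absence of Plx1 (0 in the unmodified model)
extra = 0.0
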