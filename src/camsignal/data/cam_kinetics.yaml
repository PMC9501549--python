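# Supplementary kinetic constants not printed in the model's main parameter table.
# version: 1
#
# Nine-state Ca2+-CaM rates: flash-photolysis calibration of the independent
# two-site T/R lobe scheme (N-lobe fast/low-affinity, C-lobe slow/high-affinity).
# Units: on-rates uM^-1 s^-1, off-rates s^-1.
kon_NT: 770.0
koff_NT: 1.6e5
kon_NR: 3.2e4
koff_NR: 2.2e4
kon_CT: 84.0
koff_CT: 2.6e3
kon_CR: 25.0
koff_CR: 6.5
# PDE4B / PDE4D Michaelis constants for cAMP (uM); literature values for the
# PDE4 family, shared between basal and phosphorylated forms.
Km7: 4.0
Km9: 2.0
# Fast Ca2+ -> CaNB (PP2B regulatory subunit) pre-equilibrium: half-saturation
# K1 (uM) and Hill coefficient. Only Ca-loaded CaNB presents CaNA for CaM4.
K1: 0.5
n_canb: 3.0
# Phospho-I-1 binding to PP1 (Kd = 1 nM, classic inhibitor-1 potency).
# kon uM^-1 s^-1, koff s^-1.
kon_i1pp1: 10.0
koff_i1pp1: 0.01
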