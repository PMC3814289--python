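name: erk-mapk-cascade
system_size: 6.02214076
species:
- id: MKKK
  name: MAPK kinase kinase
  initial: 90.0
- id: MKKK_P
  name: phospho-MKKK
  initial: 10.0
- id: MKK
  name: MAPK kinase
  initial: 280.0
- id: MKK_P
  name: phospho-MKK
  initial: 10.0
- id: MKK_PP
  name: bisphospho-MKK
  initial: 10.0
- id: MAPK
  name: MAPK (ERK)
  initial: 280.0
- id: MAPK_P
  name: phospho-MAPK
  initial: 10.0
- id: MAPK_PP
  name: bisphospho-MAPK
  initial: 10.0
parameters:
  V1: 2.5
  Ki: 45.0
  n: 1.0
  K1: 10.0
  V2: 0.25
  K2: 8.0
  k3: 0.025
  K3: 15.0
  k4: 0.025
  K4: 15.0
  V5: 0.75
  K5: 15.0
  V6: 0.75
  K6: 15.0
  k7: 0.025
  K7: 15.0
  k8: 0.025
  K8: 15.0
  V9: 0.5
  K9: 15.0
  V10: 0.5
  K10: 15.0
reactions:
- id: v1_MKKK_activation
  reactants:
    MKKK: 1
  products:
    MKKK_P: 1
  rate: V1 * MKKK / ((1 + (MAPK_PP / Ki)^n) * (K1 + MKKK))
- id: v2_MKKK_deactivation
  reactants:
    MKKK_P: 1
  products:
    MKKK: 1
  rate: V2 * MKKK_P / (K2 + MKKK_P)
- id: v3_MKK_phosphorylation
  reactants:
    MKK: 1
  products:
    MKK_P: 1
  rate: k3 * MKKK_P * MKK / (K3 + MKK)
- id: v4_MKKP_phosphorylation
  reactants:
    MKK_P: 1
  products:
    MKK_PP: 1
  rate: k4 * MKKK_P * MKK_P / (K4 + MKK_P)
- id: v5_MKKPP_dephosphorylation
  reactants:
    MKK_PP: 1
  products:
    MKK_P: 1
  rate: V5 * MKK_PP / (K5 + MKK_PP)
- id: v6_MKKP_dephosphorylation
  reactants:
    MKK_P: 1
  products:
    MKK: 1
  rate: V6 * MKK_P / (K6 + MKK_P)
- id: v7_MAPK_phosphorylation
  reactants:
    MAPK: 1
  products:
    MAPK_P: 1
  rate: k7 * MKK_PP * MAPK / (K7 + MAPK)
- id: v8_MAPKP_phosphorylation
  reactants:
    MAPK_P: 1
  products:
    MAPK_PP: 1
  rate: k8 * MKK_PP * MAPK_P / (K8 + MAPK_P)
- id: v9_MAPKPP_dephosphorylation
  reactants:
    MAPK_PP: 1
  products:
    MAPK_P: 1
  rate: V9 * MAPK_PP / (K9 + MAPK_PP)
- id: v10_MAPKP_dephosphorylation
  reactants:
    MAPK_P: 1
  products:
    MAPK: 1
  rate: V10 * MAPK_P / (K10 + MAPK_P)
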