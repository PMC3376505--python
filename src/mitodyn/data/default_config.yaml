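buffering:
  beta_h: 25.0
calcium:
  intercept: -0.0002
  lower: 1.0e-05
  reference: 0.00035999999999999997
  slope: -4.0e-06
  upper: 0.002
calibration:
  dpsi_target: -140.0
  dpsi_window:
  - -150.0
  - -120.0
  max_outer_iterations: 6
  nadh_ratio: 0.3
  nadh_ratio_tolerance: 0.05
  ref_load_fraction: 0.3
  ref_load_tolerance: 0.03
  share_atp: 0.6
  share_k: 0.16
  share_leak: 0.24
  share_tolerance: 0.02
clamps:
  cl_c: 5.0
  k_c: 140.0
  na_c: 10.0
  o2: 0.03
  ph_c: 7.2
  pi_c: 2.5
  pyr_c: 0.15
complex_i:
  alpha: 0.5
  energies: {}
  kf: {}
  rate_scale: 14.77322268413663
  variant: lumped
complex_iii:
  alpha: 0.5
  energies: {}
  kf: {}
  rate_scale: 1.5272710149552042
enzymes:
  AC:
    inhibition: 0.0
    ka_ca: null
    keq: 0.067
    km:
      Cit: 0.48
      IsoCit: 0.12
    vmax: 5.206608571428569
  CS:
    inhibition: 0.0
    ka_ca: null
    keq: 1000000.0
    km:
      ACoA: 0.013
      Cit: 1.6
      CoA: 0.07
      OA: 0.001
    vmax: 48.46957981138664
  FUM:
    inhibition: 0.0
    ka_ca: null
    keq: 4.4
    km:
      Fum: 0.14
      Mal: 0.3
    vmax: 2.0770987654320985
  IDH:
    inhibition: 0.0
    ka_ca: 0.001
    keq: 30.0
    km:
      IsoCit: 0.03
      NAD: 0.6
      NADH: 0.05
      aKG: 0.5
    vmax: 1.9025641502485717
  KGDHC:
    inhibition: 0.0
    ka_ca: 0.0013
    keq: 1000000.0
    km:
      CoA: 0.05
      NAD: 0.6
      NADH: 0.05
      SucCoA: 0.05
      aKG: 0.4
    vmax: 2.127379451221448
  MDH:
    inhibition: 0.0
    ka_ca: null
    keq: 2.8e-05
    km:
      Mal: 0.45
      NAD: 0.6
      NADH: 0.05
      OA: 0.0017
    vmax: 30.746148352941127
  PDH:
    inhibition: 0.0
    ka_ca: 0.001
    keq: 100000.0
    km:
      ACoA: 0.02
      CoA: 0.05
      NAD: 0.6
      NADH: 0.05
      Pyr_m: 0.06
    vmax: 1.0648739402918692
  SCS:
    inhibition: 0.0
    ka_ca: null
    keq: 3.7
    km:
      ADP_m: 2.0
      ATP_m: 1.1
      CoA: 0.056
      Pi_m: 2.5
      Suc: 1.5
      SucCoA: 0.06
    vmax: 1.3516226084587566
  SDH:
    inhibition: 0.0
    ka_ca: null
    keq: 100.0
    km:
      Fum: 1.1
      QH2_n: 1.0
      Q_n: 0.6
      Suc: 1.0
    vmax: 3.5133582260153937
load:
  k_load: 0.09130519262295082
  km_load: 0.1
membrane:
  capacitance: 0.00145
  volume_ratio: 10.0
pools:
  adenine_c: 2.5
  adenine_m: 10.0
  ci_total: 0.02
  ciii_total: 0.06
  coa_total: 0.25
  cytc_total: 0.4
  initial:
    ACoA: 0.03
    ATP_c: 2.44
    ATP_m: 2.6
    Cit: 0.25
    Cl_m: 0.026472409632125677
    CoA: 0.19
    Fum: 0.035
    IsoCit: 0.015577500000000001
    K_m: 120.0
    Mal: 0.1
    NADH: 0.6923076923076922
    Na_m: 8.0
    OA: 8.400000000000003e-06
    Pi_m: 3.8
    Pyr_m: 0.12
    QH2_n: 1.25
    QH2_p: 1.05
    Q_n: 0.75
    Q_p: 0.95
    Suc: 0.1
    SucCoA: 0.03
    aKG: 0.2
    cytc_red: 0.32
    dpsi: -140.0
    ph_m: 7.45
  nad_total: 3.0
  q_total: 4.0
schema_version: 1
transporters:
  dg0_phos: 31.9
  dpsi_leak_ref: -140.0
  k_qdiff: 5.750000000000002
  kappa_c4: 1.95
  km_ant_c: 0.2
  km_ant_m: 1.0
  km_kh_c: 30.0
  km_kh_h: 0.0002
  km_o2: 0.001
  km_pi: 2.0
  km_pyr: 0.3
  lambda_leak: 14.0
  n_a: 3.0
  p_cl: 5.0e-05
  p_h: 3830.3174369420008
  p_k: 0.0011526458364339016
  p_na: 0.00020165173516746863
  v_ant: 31.380687440830854
  v_c4: 25484.290269351106
  v_f1: 2.7583273786284086
  v_kh: 28.14312616938391
  v_nah: 1.0111828395190496
  v_pi: 31.77604813732489
  v_pyr: 2.185
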