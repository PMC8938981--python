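alpha_dop: 0.0
alpha_normal: 0.8
background: {}
background_targets:
  D1-SPN:
  - 0.1
  - 0.5
  D2-SPN:
  - 1.0
  - 2.0
  FSI:
  - 10.0
  - 20.0
  GPe-TA:
  - 12.0
  - 16.0
  GPe-TI:
  - 17.0
  - 20.0
  SNr:
  - 20.0
  - 35.0
  STN:
  - 26.0
  - 29.0
d2_modulation: false
name: PD-triphasic
neuron_params:
  D1-SPN:
    C_m: 192.0
    E_L: -83.712
    E_ex: 0.0
    E_in: -64.0
    I_e: 128.0
    V_reset: -87.2
    V_th: -37.62
    beta_EL: 0.05
    beta_Vth: 0.205
    g_L: 8.04
    kind: LIF
    t_ref: 2.0
    tau_syn_ex: 0.3
    tau_syn_in: 2.0
  D2-SPN:
    C_m: 157.0
    E_L: -85.4
    E_ex: 0.0
    E_in: -64.0
    I_e: 0.0
    V_reset: -85.4
    V_th: -45.0
    beta_EL: 0.0
    beta_Vth: 0.0
    g_L: 6.46
    kind: LIF
    t_ref: 2.0
    tau_syn_ex: 0.3
    tau_syn_in: 2.0
  FSI:
    C_m: 700.0
    E_L: -69.056
    E_ex: 0.0
    E_in: -76.0
    I_e: 0.0
    V_reset: -65.0
    V_th: -54.0
    beta_EL: -0.078
    beta_Vth: 0.0
    g_L: 16.67
    kind: LIF
    t_ref: 2.0
    tau_syn_ex: 0.3
    tau_syn_in: 2.0
  GPe-TA:
    C_m: 60.0
    Delta_T: 2.55
    E_L: -63.078480000000006
    E_ex: 0.0
    E_in: -65.0
    I_e: 1.0
    V_peak: 0.0
    V_reset: -60.0
    V_th: -54.7
    a: 2.5
    b: 105.0
    beta_EL: -0.181
    beta_Vth: 0.0
    g_L: 1.0
    kind: AdEx
    t_ref: 2.0
    tau_syn_ex: 1.0
    tau_syn_in: 5.5
    tau_w: 20.0
  GPe-TI:
    C_m: 40.0
    Delta_T: 1.7
    E_L: -63.078480000000006
    E_ex: 0.0
    E_in: -65.0
    I_e: 12.0
    V_peak: 0.0
    V_reset: -60.0
    V_th: -54.7
    a: 2.5
    b: 70.0
    beta_EL: -0.181
    beta_Vth: 0.0
    g_L: 1.0
    kind: AdEx
    t_ref: 2.0
    tau_syn_ex: 4.8
    tau_syn_in: 1.0
    tau_w: 20.0
  SNr:
    C_m: 80.0
    Delta_T: 1.6
    E_L: -59.799744
    E_ex: 0.0
    E_in: -80.0
    I_e: 0.0
    V_peak: 0.0
    V_reset: -65.0
    V_th: -55.2
    a: 3.0
    b: 200.0
    beta_EL: -0.0896
    beta_Vth: 0.0
    g_L: 3.0
    kind: AdEx
    t_ref: 2.0
    tau_syn_ex: 5.7
    tau_syn_in: 2.04
    tau_w: 20.0
  STN:
    C_m: 60.0
    E_L: -80.2
    E_ex: -10.0
    E_in: -84.0
    I_e: 1.0
    V_reset: -70.0
    V_th: -64.0
    beta_EL: 0.0
    beta_Vth: 0.0
    g_L: 10.0
    kind: LIF
    t_ref: 2.0
    tau_syn_ex: 0.33
    tau_syn_in: 1.5
projections:
  D1-SPN->D1-SPN:
    K: 364
    beta: 0.88
    delay: 1.7
    source: D1-SPN
    target: D1-SPN
    weight: -0.04439999999999999
  D1-SPN->D2-SPN:
    K: 84
    beta: 0.88
    delay: 1.7
    source: D1-SPN
    target: D2-SPN
    weight: -0.11099999999999997
  D1-SPN->SNr:
    K: 500
    beta: 0.56
    delay: 7.0
    source: D1-SPN
    target: SNr
    weight: -8.28
  D2-SPN->D1-SPN:
    K: 392
    beta: 0.88
    delay: 1.7
    source: D2-SPN
    target: D1-SPN
    weight: -0.13319999999999999
  D2-SPN->D2-SPN:
    K: 504
    beta: 0.88
    delay: 1.7
    source: D2-SPN
    target: D2-SPN
    weight: -0.10359999999999997
  D2-SPN->GPe-TI:
    K: 500
    beta: -0.48
    delay: 7.0
    source: D2-SPN
    target: GPe-TI
    weight: -1.49472
  FSI->D1-SPN:
    K: 16
    beta: 0.0
    delay: 1.7
    source: FSI
    target: D1-SPN
    weight: -2.6
  FSI->D2-SPN:
    K: 11
    beta: -0.9
    delay: 1.7
    source: FSI
    target: D2-SPN
    weight: -4.472
  FSI->FSI:
    K: 10
    beta: -1.27
    delay: 1.7
    source: FSI
    target: FSI
    weight: -0.8064
  GPe-TA->D1-SPN:
    K: 10
    beta: -1.22
    delay: 7.0
    source: GPe-TA
    target: D1-SPN
    weight: -0.03952
  GPe-TA->D2-SPN:
    K: 10
    beta: -1.15
    delay: 7.0
    source: GPe-TA
    target: D2-SPN
    weight: -0.0768
  GPe-TA->FSI:
    K: 10
    beta: -0.53
    delay: 7.0
    source: GPe-TA
    target: FSI
    weight: -0.356
  GPe-TA->GPe-TA:
    K: 5
    beta: -0.83
    delay: 1.0
    source: GPe-TA
    target: GPe-TA
    weight: -0.18304
  GPe-TA->GPe-TI:
    K: 5
    beta: -0.83
    delay: 1.0
    source: GPe-TA
    target: GPe-TI
    weight: -2.1632000000000002
  GPe-TI->FSI:
    K: 10
    beta: -0.53
    delay: 7.0
    source: GPe-TI
    target: FSI
    weight: -1.424
  GPe-TI->GPe-TA:
    K: 25
    beta: -0.83
    delay: 1.0
    source: GPe-TI
    target: GPe-TA
    weight: -0.5824
  GPe-TI->GPe-TI:
    K: 25
    beta: -0.83
    delay: 1.0
    source: GPe-TI
    target: GPe-TI
    weight: -2.1632000000000002
  GPe-TI->SNr:
    K: 32
    beta: 0.0
    delay: 3.0
    source: GPe-TI
    target: SNr
    weight: -52.5
  GPe-TI->STN:
    K: 30
    beta: -0.24
    delay: 1.0
    source: GPe-TI
    target: STN
    weight: -0.3576
  STN->GPe-TA:
    K: 30
    beta: -0.3
    delay: 2.0
    source: STN
    target: GPe-TA
    weight: 0.2976
  STN->GPe-TI:
    K: 30
    beta: -0.3
    delay: 2.0
    source: STN
    target: GPe-TI
    weight: 0.217
  STN->SNr:
    K: 30
    beta: 0.0
    delay: 4.0
    source: STN
    target: SNr
    weight: 4.78
projections_base:
  D1-SPN->D1-SPN:
    K: 364
    beta: 0.88
    delay: 1.7
    source: D1-SPN
    target: D1-SPN
    weight: -0.15
  D1-SPN->D2-SPN:
    K: 84
    beta: 0.88
    delay: 1.7
    source: D1-SPN
    target: D2-SPN
    weight: -0.375
  D1-SPN->SNr:
    K: 500
    beta: 0.56
    delay: 7.0
    source: D1-SPN
    target: SNr
    weight: -15.0
  D2-SPN->D1-SPN:
    K: 392
    beta: 0.88
    delay: 1.7
    source: D2-SPN
    target: D1-SPN
    weight: -0.45
  D2-SPN->D2-SPN:
    K: 504
    beta: 0.88
    delay: 1.7
    source: D2-SPN
    target: D2-SPN
    weight: -0.35
  D2-SPN->GPe-TI:
    K: 500
    beta: -0.48
    delay: 7.0
    source: D2-SPN
    target: GPe-TI
    weight: -1.08
  FSI->D1-SPN:
    K: 16
    beta: 0.0
    delay: 1.7
    source: FSI
    target: D1-SPN
    weight: -2.6
  FSI->D2-SPN:
    K: 11
    beta: -0.9
    delay: 1.7
    source: FSI
    target: D2-SPN
    weight: -2.6
  FSI->FSI:
    K: 10
    beta: -1.27
    delay: 1.7
    source: FSI
    target: FSI
    weight: -0.4
  GPe-TA->D1-SPN:
    K: 10
    beta: -1.22
    delay: 7.0
    source: GPe-TA
    target: D1-SPN
    weight: -0.02
  GPe-TA->D2-SPN:
    K: 10
    beta: -1.15
    delay: 7.0
    source: GPe-TA
    target: D2-SPN
    weight: -0.04
  GPe-TA->FSI:
    K: 10
    beta: -0.53
    delay: 7.0
    source: GPe-TA
    target: FSI
    weight: -0.25
  GPe-TA->GPe-TA:
    K: 5
    beta: -0.83
    delay: 1.0
    source: GPe-TA
    target: GPe-TA
    weight: -0.11
  GPe-TA->GPe-TI:
    K: 5
    beta: -0.83
    delay: 1.0
    source: GPe-TA
    target: GPe-TI
    weight: -1.3
  GPe-TI->FSI:
    K: 10
    beta: -0.53
    delay: 7.0
    source: GPe-TI
    target: FSI
    weight: -1.0
  GPe-TI->GPe-TA:
    K: 25
    beta: -0.83
    delay: 1.0
    source: GPe-TI
    target: GPe-TA
    weight: -0.35
  GPe-TI->GPe-TI:
    K: 25
    beta: -0.83
    delay: 1.0
    source: GPe-TI
    target: GPe-TI
    weight: -1.3
  GPe-TI->SNr:
    K: 32
    beta: 0.0
    delay: 3.0
    source: GPe-TI
    target: SNr
    weight: -52.5
  GPe-TI->STN:
    K: 30
    beta: -0.24
    delay: 1.0
    source: GPe-TI
    target: STN
    weight: -0.3
  STN->GPe-TA:
    K: 30
    beta: -0.3
    delay: 2.0
    source: STN
    target: GPe-TA
    weight: 0.24
  STN->GPe-TI:
    K: 30
    beta: -0.3
    delay: 2.0
    source: STN
    target: GPe-TI
    weight: 0.175
  STN->SNr:
    K: 30
    beta: 0.0
    delay: 4.0
    source: STN
    target: SNr
    weight: 4.78
stimulus_weights: {}
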