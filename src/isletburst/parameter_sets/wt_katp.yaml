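variant: WT_KATP
parameters:
  Cm:
    value: 5300.0
    unit: fF
    source: package calibration
  gK:
    value: 2700.0
    unit: pS
    source: package calibration
  gCa:
    value: 1350.0
    unit: pS
    source: package calibration
  gKCa:
    value: 10.0
    unit: pS
    source: package calibration
  gKATP_bar:
    value: 10000.0
    unit: pS
    source: package calibration
  gKir:
    value: 0.0
    unit: pS
    source: package calibration
  gleak:
    value: 0.0
    unit: pS
    source: printed value for the leak/K(Ca) knockout variant (32.5 pS)
  VK:
    value: -75.0
    unit: mV
    source: package calibration
  VCa:
    value: 25.0
    unit: mV
    source: package calibration
  vm:
    value: -22.0
    unit: mV
    source: package calibration
  sm:
    value: 7.5
    unit: mV
    source: package calibration
  vn:
    value: -16.0
    unit: mV
    source: package calibration
  sn:
    value: 5.0
    unit: mV
    source: package calibration
  tau_n:
    value: 8.0
    unit: ms
    source: package calibration
  Kc:
    value: 0.2
    unit: uM
    source: package calibration
  fcyt:
    value: 0.01
    unit: '1'
    source: package calibration
  alpha:
    value: 4.5e-06
    unit: uM/(fA*ms)
    source: package calibration
  kpmca:
    value: 0.06
    unit: 1/ms
    source: package calibration
  kleak:
    value: 0.0005
    unit: 1/ms
    source: package calibration
  kSERCA:
    value: 0.4
    unit: 1/ms
    source: package calibration
  fer:
    value: 0.01
    unit: '1'
    source: package calibration
  Vcte:
    value: 5.0
    unit: '1'
    source: package calibration
  VKir:
    value: -50.0
    unit: mV
    source: package calibration
  sKir:
    value: 10.0
    unit: mV
    source: package calibration
  alpha_camp:
    value: 0.08
    unit: '1'
    source: package calibration
  beta_camp:
    value: 0.9
    unit: '1'
    source: package calibration
  Kcamp:
    value: 0.5
    unit: uM
    source: package calibration
  vAC_bar:
    value: 0.00015
    unit: uM/ms
    source: package calibration
  alphaAC:
    value: 0.6
    unit: '1'
    source: package calibration
  betaAC:
    value: 0.4
    unit: '1'
    source: package calibration
  KACca:
    value: 0.25
    unit: uM
    source: package calibration
  beta_amp:
    value: 1.0
    unit: '1'
    source: package calibration
  Kamp:
    value: 60.0
    unit: uM
    source: package calibration
  amp_exp:
    value: 2.0
    unit: '1'
    source: package calibration
  vPDE_bar:
    value: 0.0007
    unit: uM/ms
    source: package calibration
  alphaPDE:
    value: 0.3
    unit: '1'
    source: package calibration
  betaPDE:
    value: 0.4
    unit: '1'
    source: package calibration
  KPDEca:
    value: 0.25
    unit: uM
    source: package calibration
  KPDEcamp:
    value: 2.0
    unit: uM
    source: package calibration
  JGK:
    value: 0.09
    unit: uM/ms
    source: printed glucokinase rate (0.09 WT, 0.14 KO)
  vPFK:
    value: 1.5
    unit: uM/ms
    source: package calibration
  lambda_pfk:
    value: 0.01
    unit: '1'
    source: package calibration
  Kamp_pfk:
    value: 500.0
    unit: uM
    source: package calibration
  Kfbp_pfk:
    value: 1.0
    unit: uM
    source: package calibration
  Kf6p_pfk:
    value: 1200000000.0
    unit: uM^2
    source: package calibration
  Katp_pfk:
    value: 30000.0
    unit: uM^2
    source: package calibration
  f13:
    value: 1.0
    unit: '1'
    source: package calibration
  f23:
    value: 0.1
    unit: '1'
    source: package calibration
  f41:
    value: 20.0
    unit: '1'
    source: package calibration
  f42:
    value: 20.0
    unit: '1'
    source: package calibration
  f43:
    value: 2.0
    unit: '1'
    source: package calibration
  kgpdh:
    value: 0.1
    unit: uM/ms
    source: package calibration
  kFBP:
    value: 0.8
    unit: '1'
    source: printed (0.8 WT, 0.95 KO)
  f6p_frac:
    value: 0.3
    unit: '1'
    source: package calibration
  Atot:
    value: 3000.0
    unit: uM
    source: package calibration
  tau_a:
    value: 600000.0
    unit: ms
    source: package calibration
  r_base:
    value: 1.15
    unit: '1'
    source: package calibration
  r1:
    value: 0.6
    unit: uM/ms
    source: package calibration
  w_pmca:
    value: 0.2
    unit: '1'
    source: package calibration
  vgamma:
    value: 4.0
    unit: '1'
    source: package calibration
  kgamma:
    value: 0.1
    unit: uM/ms
    source: package calibration
  kdd:
    value: 17.0
    unit: uM
    source: package calibration
  ktd:
    value: 26.0
    unit: uM
    source: package calibration
  ktt:
    value: 1.0
    unit: uM
    source: package calibration
  frac_mgadp:
    value: 0.165
    unit: '1'
    source: package calibration
  frac_adp3:
    value: 0.135
    unit: '1'
    source: package calibration
  frac_atp4:
    value: 0.05
    unit: '1'
    source: package calibration
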