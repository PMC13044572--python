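label: onc(phi=0,eta=0)
trials:
- n_treatment: 400
  n_control: 370
  tau_treatment: 2.5
  tau_control: 1.6666666666666667
  historical: false
- n_treatment: 680
  n_control: 500
  tau_treatment: 5.416666666666667
  tau_control: 5.416666666666667
  historical: false
- n_treatment: 245
  n_control: 240
  tau_treatment: 2.5
  tau_control: 2.5
  historical: false
- n_treatment: 190
  n_control: 175
  tau_treatment: 1.25
  tau_control: 1.25
  historical: false
- n_treatment: 350
  n_control: 350
  tau_treatment: 2.9166666666666665
  tau_control: 2.9166666666666665
  historical: false
- n_treatment: 440
  n_control: 440
  tau_treatment: 2.0833333333333335
  tau_control: 1.6666666666666667
  historical: false
- n_treatment: 190
  n_control: 180
  tau_treatment: 2.0833333333333335
  tau_control: 2.0833333333333335
  historical: false
- n_treatment: 330
  n_control: 340
  tau_treatment: 2.0833333333333335
  tau_control: 2.0833333333333335
  historical: false
- n_treatment: 350
  n_control: 350
  tau_treatment: 0.8333333333333334
  tau_control: 0.8333333333333334
  historical: false
anchor: treatment
nu1: -3.912023005428146
sigma1: 1.2
nu2: -0.6931471805599453
sigma2: 0.0
nu3: -0.6931471805599453
sigma3: 0.0
q0: 0.01
q1: 0.01
phi: 0.0
eta: 0.0
event_shape: 1.0
time_unit: years
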