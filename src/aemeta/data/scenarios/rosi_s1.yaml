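label: rosi(phi=0,eta=0)
trials:
- n_treatment: 300
  n_control: 50
  tau_treatment: 0.23076923076923078
  tau_control: 0.23076923076923078
  historical: false
- n_treatment: 150
  n_control: 150
  tau_treatment: 0.23076923076923078
  tau_control: 0.23076923076923078
  historical: false
- n_treatment: 150
  n_control: 75
  tau_treatment: 0.5
  tau_control: 0.5
  historical: false
- n_treatment: 150
  n_control: 75
  tau_treatment: 0.5
  tau_control: 0.5
  historical: false
- n_treatment: 150
  n_control: 75
  tau_treatment: 0.5
  tau_control: 0.5
  historical: false
- n_treatment: 50
  n_control: 50
  tau_treatment: 1.0
  tau_control: 1.0
  historical: false
- n_treatment: 0
  n_control: 100
  tau_treatment: 0.5
  tau_control: 0.5
  historical: true
- n_treatment: 0
  n_control: 100
  tau_treatment: 0.5
  tau_control: 0.5
  historical: true
- n_treatment: 0
  n_control: 100
  tau_treatment: 0.5
  tau_control: 0.5
  historical: true
- n_treatment: 0
  n_control: 100
  tau_treatment: 0.5
  tau_control: 0.5
  historical: true
- n_treatment: 0
  n_control: 100
  tau_treatment: 0.5
  tau_control: 0.5
  historical: true
- n_treatment: 0
  n_control: 100
  tau_treatment: 0.5
  tau_control: 0.5
  historical: true
- n_treatment: 0
  n_control: 100
  tau_treatment: 0.5
  tau_control: 0.5
  historical: true
- n_treatment: 0
  n_control: 100
  tau_treatment: 0.5
  tau_control: 0.5
  historical: true
- n_treatment: 0
  n_control: 100
  tau_treatment: 0.5
  tau_control: 0.5
  historical: true
- n_treatment: 0
  n_control: 100
  tau_treatment: 0.5
  tau_control: 0.5
  historical: true
- n_treatment: 0
  n_control: 100
  tau_treatment: 0.5
  tau_control: 0.5
  historical: true
- n_treatment: 0
  n_control: 100
  tau_treatment: 0.5
  tau_control: 0.5
  historical: true
anchor: control
nu1: -0.6931471805599453
sigma1: 0.0
nu2: -0.6931471805599453
sigma2: 0.0
nu3: -0.6931471805599453
sigma3: 0.0
q0: 0.35
q1: 0.35
phi: 0.0
eta: 0.0
event_shape: 1.0
time_unit: years
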