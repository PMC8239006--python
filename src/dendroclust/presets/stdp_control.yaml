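tau_W: 6000.0
tau_P: 5.0
tau_B: 5.0
tau_Y: 1.0
tau_M: 60.0
tau_u: 1.0
tau_v: 60.0
eta: 0.3
phi: 0.6
sigma_c: 6.0
alpha: 1.0
beta: 1.0
W_thr: 0.02
nu: 0.2
x_dur: 50.0
A_th: 25.0
bap_prob: 0.25
B_amp: 5.0
sigma_bap: 75.0
bap_refractory: 200.0
bap_per_step: false
bap_burst_events: 10
gamma: 0.0
c1: 0.5
c2: 35.0
c3: 0.125
coop_on: false
coop_spacing: 10.0
coop_timing: 100.0
coop_min_count: 3
coop_include_self: false
gaba_mode: 'off'
switch_day: 4.0
preset: stdp-control
proximity_cutoff_sigmas: 5.0
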