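# Inhibitory population with fast synapses: sustained ING oscillation
[model]
kind = qif-fre
[params]
tau_m = 10
tau_d = 5
J = 21
Theta = 4
Delta = 0.3
[init]
r_hz = 5
v = 0
s_hz = 5
[run]
duration_ms = 2000
seed = 0
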