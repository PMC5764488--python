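# Wang-Buzsaki network, tau_d = 50 ms
[model]
kind = wb-net
[wb]
N = 1000
I_bar = 0.5
sigma = 0.01
k = 6
tau_d = 50
dt = 0.001
init_voltage_center = -62
init_voltage_halfwidth = 5
[run]
duration_ms = 2000
smoothing_tau_s_ms = 2
seed = 0
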