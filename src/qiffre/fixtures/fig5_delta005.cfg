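# Homogeneous WB sweep (delta = sigma/I_bar = 0.05)
[model]
kind = wb-net
[wb]
N = 1000
I_bar = 0.2
sigma = 0.01
dt = 0.001
[sweep]
delta = 0.05
tau_d_grid = 1 2 5 10 20 40
k_grid = 1 2 4 6 8 12
direction = increasing
duration_ms = 2000
transient_ms = 1000
window_ms = 200
n_windows = 5
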