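# Slow synapses under periodic drive Theta(t) = 4 + (1 + sin(2 pi t/T))^3
[model]
kind = qif-fre
[params]
tau_m = 10
tau_d = 100
J = 21
Theta = 4
Delta = 0.3
[forcing]
kind = sinusoid-cubed
base = 4
period_ms = 100
[run]
duration_ms = 3000
transient_ms = 1000
seed = 0
[compare]
models = qif-fre h-fre slow-reduction
channels = r s
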