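# Benchmarking-mode demo: synthetic DUD-E-style haystack with a planted
# score signal, screened by the planted-score engine and a random control.
[run]
mode = benchmark
target_id = demo
n_chunks = 3
seed = 7
output_dir = demo_run

[library]
synthetic = true
n_actives = 20
decoys_per_active = 10
signal_mu = 2.0
noise_sd = 1.0

[prepare]
backend = identity
n_conformers = 200

[engines]
names = planted, random

[benchmark]
ef_fractions = 0.01, 0.05
consensus = rank_sum
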