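# Mediation-ratio sweep on sparse random networks (reference parameters).
N: 100
network_family: erdos_renyi
mean_degree: 1.0
seed: 42
sweep:
  r: [0.0, 0.35, 0.7, 1.0]
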