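pools: [I, II]
chains:
  - id: X1
    n_sites: 2
    rates: [0.8, 1.0, 1.2]
    source_pool: I
    sink_pool: II
    input_function: {name: tanh, params: {}}
  - id: Y1
    n_sites: 2
    rates: [1.0, 2.0, 1.0]
    source_pool: II
    sink_pool: I
    input_function: {name: identity, params: {}}
initial_state: [0.5, 0.5, 0.5, 0.5, 0.0, 0.0]
total_particles: 2
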