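pools: [P1, P2, P3]
chains:
  - id: R1
    n_sites: 2
    rates: [0.8, 1.0, 2.0]
    source_pool: P1
    sink_pool: P2
    input_function: {name: tanh, params: {}}
  - id: R2
    n_sites: 2
    rates: [1.0, 1.2, 0.1]
    source_pool: P2
    sink_pool: P3
    input_function: {name: tanh, params: {}}
  - id: R3
    n_sites: 2
    rates: [0.1, 0.5, 1.0]
    source_pool: P3
    sink_pool: P1
    input_function: {name: identity, params: {}}
initial_state: [0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 0.0, 0.0, 1.0]
total_particles: 4
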