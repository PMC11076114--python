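pools: [I, II]
chains:
  - id: X1
    n_sites: 10
    rates: [1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1]
    source_pool: I
    sink_pool: II
    input_function: {name: identity, params: {}}
  - id: Y1
    n_sites: 5
    rates: [1, 1, 1, 1, 1, 1]
    source_pool: II
    sink_pool: I
    input_function: {name: identity, params: {}}
  - id: Y2
    n_sites: 5
    rates: [1, 1, 1, 1, 1, 1]
    source_pool: II
    sink_pool: I
    input_function: {name: identity, params: {}}
total_particles: 0.4
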