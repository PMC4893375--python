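# Three-layer colon tissue model: parameter ranges per layer.
# v_hb, s are fractions [0,1]; a_mie in cm^-1; d in micrometers.
# a_mie given as mean +/- halfwidth (uniform by default).
name: colon
c_hb_gram_per_liter: 120.0
shared_oxygenation: true
total_thickness_um_max: null
layers:
  - v_hb: [0.0, 0.1]
    s: [0.0, 1.0]
    a_mie: {mean: 18.9, halfwidth: 10.2}
    b: 1.286
    g: [0.8, 0.95]
    n_refr: 1.36
    d: [600.0, 1010.0]
  - v_hb: [0.0, 0.1]
    s: [0.0, 1.0]
    a_mie: {mean: 18.9, halfwidth: 10.2}
    b: 1.286
    g: [0.8, 0.95]
    n_refr: 1.36
    d: [415.0, 847.0]
  - v_hb: [0.0, 0.1]
    s: [0.0, 1.0]
    a_mie: {mean: 18.9, halfwidth: 10.2}
    b: 1.286
    g: [0.8, 0.95]
    n_refr: 1.38
    d: [395.0, 603.0]
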