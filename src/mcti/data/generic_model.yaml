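# Three-layer generic tissue model with wide parameter ranges,
# used for domain-switch robustness experiments.
# Layer thicknesses are renormalized so the slab totals at most 2 mm.
name: generic
c_hb_gram_per_liter: 120.0
shared_oxygenation: true
total_thickness_um_max: 2000.0
layers:
  - v_hb: [0.0, 1.0]
    s: [0.0, 1.0]
    a_mie: {mean: 18.9, halfwidth: 10.2}
    b: 1.286
    g: [0.8, 0.95]
    n_refr: [1.33, 1.54]
    d: [0.0, 2000.0]
  - v_hb: [0.0, 1.0]
    s: [0.0, 1.0]
    a_mie: {mean: 18.9, halfwidth: 10.2}
    b: 1.286
    g: [0.8, 0.95]
    n_refr: [1.33, 1.54]
    d: [0.0, 2000.0]
  - v_hb: [0.0, 1.0]
    s: [0.0, 1.0]
    a_mie: {mean: 18.9, halfwidth: 10.2}
    b: 1.286
    g: [0.8, 0.95]
    n_refr: [1.33, 1.54]
    d: [0.0, 2000.0]
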