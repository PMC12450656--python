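{
  "beta": 0.5,
  "gamma": 0.1,
  "kappa": 3.0,
  "delta": 1.0,
  "alpha": 0.65,
  "rho": 1.0,
  "mu": 0.1,
  "sigma": 0.3,
  "eta": 0.1,
  "x0": 0.35,
  "y0": 0.08,
  "t_end": 50.0
}
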