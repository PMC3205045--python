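{
  "description": "Token classes for the chemical locant-prefix automaton: one or more components separated by commas, terminated by a hyphen.",
  "digit_runs": true,
  "components": {
    "greek_names": ["alpha", "beta", "gamma", "delta", "epsilon", "zeta", "eta", "theta", "iota", "kappa", "lambda", "mu", "nu", "xi", "omicron", "pi", "rho", "sigma", "tau", "upsilon", "phi", "chi", "psi", "omega"],
    "greek_symbols": ["α", "β", "γ", "δ", "ε", "ζ", "η", "θ", "ι", "κ", "λ", "μ", "ν", "ξ", "ο", "π", "ρ", "σ", "τ", "υ", "φ", "χ", "ψ", "ω"],
    "stereo": ["R", "S", "E", "Z"],
    "geometry": ["cis", "trans"],
    "ring_position": ["o", "m", "p"],
    "hetero_locants": ["N", "O", "S"]
  }
}
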