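{
  "_comment": "Quintic hue-angle deviation presets, coefficients from degree 5 down to the constant, evaluated in b = alpha/100. 'published-oli' is the complete Landsat-8 OLI deviation polynomial (default); 'as-printed' ends in a bare constant and 'linear-final-term' ends in a linear term with zero constant, two readings of the same truncated coefficient listing.",
  "published-oli": [-52.16, 373.81, -981.83, 1134.19, -533.61, 76.72],
  "linear-final-term": [-52.16, 373.81, -981.83, 1134.19, -533.61, 0.0],
  "as-printed": [-52.16, 373.81, -981.83, 1134.19, 0.0, -533.61]
}
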