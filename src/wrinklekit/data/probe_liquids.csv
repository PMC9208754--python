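name,gamma_total,gamma_d,gamma_p
water,72.8,21.8,51.0
hexadecane,26.35,26.35,0.0
nitromethane,36.8,22.0,14.8
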