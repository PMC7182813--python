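name,gamma_total,gamma_lw,gamma_ab,gamma_plus,gamma_minus
water,72.8,21.8,51.0,25.5,25.5
formamide,58.0,39.0,19.0,2.28,39.6
methylene iodide,50.8,50.8,0,0,0
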