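wavelength_nm,eps_hbo,eps_hbr
730,427.0,1561.0
756,554.0,1328.0
796,792.0,814.0
866,1103.0,714.0
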