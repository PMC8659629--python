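sample_id,k_h_per_sqrt_min,thickness_mm,D_mm2_per_s
F1,4.13e-3,7.55,4.051e-6
F2,6.23e-3,5.67,5.199e-6
F3,5.48e-3,5.22,3.421e-6
F4,3.18e-3,2.07,0.181e-6
F5,5.77e-3,9.14,11.58e-6
F6,5.07e-3,4.91,2.582e-6
F7,5.44e-3,5.42,3.622e-6
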