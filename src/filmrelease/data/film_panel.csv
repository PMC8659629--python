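sample_id,thickness_mm,loaded_mg,released_max,swelling_pct,yield_pct
F1,7.55,12.6,10.24,238,86.1
F2,5.67,16.2,15.41,418,68.1
F3,5.22,13.3,12.05,409,77.9
F4,2.07,16.1,12.44,442,25.9
F5,9.14,17.9,17.65,957,25.2
F6,4.91,16.2,13.35,327,71.0
F7,5.42,10.5,9.03,292,38.6
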