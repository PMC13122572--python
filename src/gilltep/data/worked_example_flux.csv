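fish_id,temp_C,mass_g,volume_L,t0_h,tf_h,R0_cpm_per_L,Rf_cpm_per_L,Na0_umol_per_L,Naf_umol_per_L
fish01,27,2.0,0.07,0,1,1.0e6,9.0e5,63,62
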