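name,pH,DOC_mg_L,DIC_mg_L,Na_umol_L,Ca_umol_L,K_umol_L,Mg_umol_L,Cl_umol_L,NH4_umol_L,conductivity_uS_cm,temp_C
INPA,7.0,0.59,0.30,63,5,12,1,11,0,17,27
Rio Negro,4.0,11.2,0.21,12,8,6,3,10,0,11,27
Rio Solimoes,6.7,5.3,6.63,117,697,21,43,76,0,70,27
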