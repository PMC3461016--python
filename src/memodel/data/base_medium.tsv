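# Base-medium ion/gas exchange reactions opened for free uptake
EX_h2s_e
EX_ca2_e
EX_cl_e
EX_co2_e
EX_cobalt2_e
EX_cu2_e
EX_fe2_e
EX_fe3_e
EX_h2o_e
EX_h_e
EX_k_e
EX_mg2_e
EX_mn2_e
EX_mobd_e
EX_na1_e
EX_tungs_e
EX_zn2_e
EX_cbl1_e
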