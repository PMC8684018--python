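site_group,age_band,sex,race,count
all_excl_bcc_scc,all,men,all,51472
all_excl_bcc_scc,all,persons,all,103408
all_excl_bcc_scc,all,persons,hispanic,22642
all_excl_bcc_scc,all,persons,nh_black,12020
all_excl_bcc_scc,all,persons,nh_white,65214
all_excl_bcc_scc,all,persons,other,3532
all_excl_bcc_scc,all,women,all,51936
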