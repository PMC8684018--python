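factor,sex_stratum,site,rr,increment,unit,direction,ci_includes_null
calcium,men,colorectal,0.93,200.0,mg_per_day,protective,false
calcium,persons,colorectal,0.94,200.0,mg_per_day,protective,false
calcium,women,colorectal,0.93,200.0,mg_per_day,protective,false
fiber,men,colorectal,0.89,10.0,g_per_day,protective,false
fiber,persons,colorectal,0.93,10.0,g_per_day,protective,true
fiber,women,colorectal,0.91,10.0,g_per_day,protective,false
processed_meat,men,colorectal,1.11,50.0,g_per_day,detrimental,true
processed_meat,persons,colorectal,1.16,50.0,g_per_day,detrimental,false
processed_meat,women,colorectal,1.18,50.0,g_per_day,detrimental,true
red_meat,men,colorectal,1.28,100.0,g_per_day,detrimental,true
red_meat,persons,colorectal,1.12,100.0,g_per_day,detrimental,true
red_meat,women,colorectal,1.02,100.0,g_per_day,detrimental,true
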