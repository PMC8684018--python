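factor,sex,race,nonadherence_pct
red_meat,men,all,59.9
processed_meat,men,all,88.1
fiber,men,all,88.0
calcium,men,all,53.4
red_meat,women,all,45.4
processed_meat,women,all,83.9
fiber,women,all,95.6
calcium,women,all,71.7
red_meat,persons,all,52.7
processed_meat,persons,all,86.0
fiber,persons,all,92.0
calcium,persons,all,63.0
red_meat,men,nh_white,63.9
processed_meat,men,nh_white,91.6
fiber,men,nh_white,87.8
calcium,men,nh_white,49.5
red_meat,women,nh_white,48.7
processed_meat,women,nh_white,85.9
fiber,women,nh_white,95.6
calcium,women,nh_white,69.3
red_meat,persons,nh_white,56.4
processed_meat,persons,nh_white,88.8
fiber,persons,nh_white,91.9
calcium,persons,nh_white,59.9
red_meat,men,nh_black,49.0
processed_meat,men,nh_black,86.6
fiber,men,nh_black,96.4
calcium,men,nh_black,67.4
red_meat,women,nh_black,37.6
processed_meat,women,nh_black,86.7
fiber,women,nh_black,98.3
calcium,women,nh_black,86.6
red_meat,persons,nh_black,42.9
processed_meat,persons,nh_black,86.6
fiber,persons,nh_black,97.5
calcium,persons,nh_black,78.2
red_meat,men,hispanic,52.8
processed_meat,men,hispanic,84.9
fiber,men,hispanic,79.9
calcium,men,hispanic,63.6
red_meat,women,hispanic,40.8
processed_meat,women,hispanic,79.8
fiber,women,hispanic,92.9
calcium,women,hispanic,69.0
red_meat,persons,hispanic,47.3
processed_meat,persons,hispanic,82.5
fiber,persons,hispanic,86.6
calcium,persons,hispanic,66.4
red_meat,men,other,53.8
processed_meat,men,other,62.5
fiber,men,other,89.3
calcium,men,other,57.2
red_meat,women,other,36.6
processed_meat,women,other,67.9
fiber,women,other,94.0
calcium,women,other,74.6
red_meat,persons,other,44.9
processed_meat,persons,other,65.3
fiber,persons,other,91.7
calcium,persons,other,66.2
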