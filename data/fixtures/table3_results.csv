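race,sex,factor,colorectal_paf_pct,allcancer_paf_pct,allcancer_excess_cases
all,men,red_meat,6.5,0.7,365
all,men,processed_meat,9.0,1.0,505
all,men,fiber,12.3,1.3,695
all,men,calcium,6.6,0.7,370
all,men,all_factors,34.4,3.8,1935
all,women,red_meat,0.3,0.0,14
all,women,processed_meat,11.1,1.0,497
all,women,fiber,12.1,1.0,541
all,women,calcium,9.9,0.8,441
all,women,all_factors,33.5,2.9,1493
all,persons,red_meat,3.8,0.4,379
all,persons,processed_meat,9.9,1.0,1002
all,persons,fiber,12.3,1.2,1236
all,persons,calcium,8.0,0.8,811
all,persons,all_factors,34.0,3.3,3428
nh_white,men,red_meat,6.8,0.7,223
nh_white,men,processed_meat,9.4,0.9,308
nh_white,men,fiber,12.1,1.2,393
nh_white,men,calcium,5.8,0.6,190
nh_white,men,all_factors,34.2,3.4,1114
nh_white,women,red_meat,0.3,0.0,9
nh_white,women,processed_meat,11.3,0.9,300
nh_white,women,fiber,12.0,1.0,317
nh_white,women,calcium,9.3,0.8,248
nh_white,women,all_factors,32.9,2.7,874
nh_white,persons,red_meat,3.9,0.4,232
nh_white,persons,processed_meat,10.3,0.9,608
nh_white,persons,fiber,12.0,1.1,711
nh_white,persons,calcium,7.4,0.7,438
nh_white,persons,all_factors,33.6,3.1,1989
nh_black,men,red_meat,5.8,0.7,41
nh_black,men,processed_meat,9.5,1.1,68
nh_black,men,fiber,14.9,1.8,106
nh_black,men,calcium,9.5,1.1,68
nh_black,men,all_factors,39.7,4.7,283
nh_black,women,red_meat,0.2,0.0,1
nh_black,women,processed_meat,12.7,1.3,79
nh_black,women,fiber,13.8,1.4,86
nh_black,women,calcium,12.9,1.3,81
nh_black,women,all_factors,39.6,4.1,248
nh_black,persons,red_meat,3.2,0.4,43
nh_black,persons,processed_meat,11.0,1.2,147
nh_black,persons,fiber,14.3,1.6,192
nh_black,persons,calcium,11.1,1.2,149
nh_black,persons,all_factors,39.6,4.4,531
hispanic,men,red_meat,5.2,0.7,78
hispanic,men,processed_meat,7.4,1.0,112
hispanic,men,fiber,11.5,1.6,173
hispanic,men,calcium,9.8,1.4,148
hispanic,men,all_factors,34.0,4.8,511
hispanic,women,red_meat,0.3,0.0,3
hispanic,women,processed_meat,10.4,0.9,107
hispanic,women,fiber,11.6,1.0,119
hispanic,women,calcium,10.2,0.9,105
hispanic,women,all_factors,32.5,2.8,334
hispanic,persons,red_meat,3.2,0.4,81
hispanic,persons,processed_meat,8.7,1.0,219
hispanic,persons,fiber,11.6,1.2,292
hispanic,persons,calcium,10.0,1.1,253
hispanic,persons,all_factors,33.4,3.7,845
other,men,red_meat,5.3,0.5,8
other,men,processed_meat,4.0,0.4,6
other,men,fiber,12.4,1.1,18
other,men,calcium,7.2,0.6,11
other,men,all_factors,28.9,2.5,43
other,women,red_meat,0.1,0.0,0
other,women,processed_meat,6.6,0.5,10
other,women,fiber,11.4,1.0,17
other,women,calcium,10.9,0.9,17
other,women,all_factors,28.9,2.4,44
other,persons,red_meat,2.6,0.2,8
other,persons,processed_meat,5.3,0.5,16
other,persons,fiber,11.9,1.0,36
other,persons,calcium,9.1,0.8,27
other,persons,all_factors,28.9,2.5,87
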