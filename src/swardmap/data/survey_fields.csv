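campaign,farm,field,area_ha,acq_time_s,images,density_per_ha,speed_ha_per_h
May 2018,A,1,11.3,2675,2223,197,15.3
May 2018,A,2,18.6,4021,3398,183,16.7
May 2018,A,3,8.1,1384,1188,145,21.1
May 2018,A,4,7.1,1610,1330,185,15.9
May 2018,B,1,14.2,2998,2025,143,17.1
May 2018,B,2,4.8,1070,723,148,16.1
May 2018,B,3,9.2,2443,1202,135,13.6
May 2018,B,4,2.2,650,1202,135,12.2
Oct 2018,A,1,11.3,2078,1380,122,19.6
Oct 2018,A,2,45.8,1696,1422,31,97.2
Oct 2018,A,3,16.9,2965,2423,143,20.5
Oct 2018,A,4,14.6,2809,2170,148,18.7
Oct 2018,A,5,12.5,2651,2163,173,17.0
Oct 2018,C,1,9.4,2826,1878,200,12.0
Oct 2018,C,2,20.5,4692,3324,162,15.7
Oct 2018,C,3,18.8,3526,2999,160,19.2
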