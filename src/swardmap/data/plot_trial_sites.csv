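site,cuts_per_season,n_plots,years_since_establishment,sample_years,latitude,longitude,samples_nikon_d810a_led,samples_sony_a7_ring,samples_sony_a7_speedlight,total_samples
A,4,60,1-4,2017,56.4957,9.5693,179,60,0,239
B,4,200,1-2,2017-18,55.3397,12.3808,83,113,0,196
C,5,48,2,2019,55.5370,8.4952,0,180,60,240
D,5,48,2,2019,56.1702,8.7816,0,240,0,240
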