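row_index,n,ed_mean,ed_sd,lim_mean,lim_sd,nrf_mean,nrf_sd,p_dairy_first,p_fruit_first,water_lead,p_fvn_extra,kind
1,6,59,22,16.09,6.16,37.67,24.48,1.0,0.0,0,0.0,milk
2,13,293,114,22.95,10.31,14.38,15.99,1.0,0.0,0,0.0,cheese
3,21,96,26,23.38,8.10,25.49,29.30,1.0,0.0,0,0.4,yogurt
4,18,80,18,18.20,8.26,30.25,18.59,1.0,0.0,0,0.4,yogurt
5,16,504,97,14.28,9.89,2.72,13.99,0.0,0.0,0,1.0,nuts
6,2,428,29,13.82,4.75,13.57,31.59,0.0,0.0,0,0.0,bakery
7,6,534,22,8.60,2.97,1.98,9.60,0.0,0.0,0,0.0,chips_potato
8,4,508,24,7.08,3.82,-1.93,3.94,0.0,0.0,0,0.0,chips_corn
9,2,541,21,11.41,1.64,-0.62,7.24,0.0,0.0,0,0.0,popcorn
10,10,463,36,11.59,3.84,0.66,8.11,0.0,0.0,0,0.0,crackers
11,15,390,35,11.49,6.72,22.06,21.03,0.0,0.0,0,0.6,bar
12,2,378,40,13.81,13.88,42.01,2.61,0.0,0.0,0,1.0,bar
13,27,438,55,22.42,7.86,-9.53,11.46,0.0,0.0,0,0.0,cake
14,19,517,34,32.02,8.16,-21.79,7.63,0.0,0.0,0,0.0,candy_choc
15,27,331,68,12.67,13.83,22.38,44.44,0.0,0.4,0,0.0,candy_fruit
16,8,209,80,31.72,5.19,-11.79,11.39,0.0,0.0,0,0.0,ice_cream
17,16,140,47,30.22,8.69,-2.62,17.09,0.75,0.0,0,0.0,pudding
18,2,108,35,35.75,2.62,26.85,58.33,0.0,0.0,0,0.0,ices
19,18,79,71,2.69,7.24,48.88,45.87,0.0,1.0,0,0.0,fruit
20,2,316,23,0.59,0.29,19.58,2.76,0.0,1.0,0,0.0,dried_fruit
21,7,70,8,10.08,15.86,40.62,36.78,0.0,1.0,0,0.0,fruit_salad
22,7,48,2,0.33,0.26,67.55,24.11,0.0,1.0,1,0.0,juice
23,5,59,55,44.61,17.25,-43.98,16.94,0.0,0.0,0,0.0,soda
24,8,40,10,30.46,18.51,-1.90,38.57,0.0,0.0,0,0.0,fruit_drink
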