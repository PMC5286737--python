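sheep_id,rfa_id,power_w,duration_s,energy_j,temp_max_degc,td_d1_mm,td_d2_mm,t1w_d1_mm,t1w_d2_mm
1,1,60,60,3600,30,9,4,9,5
1,2,60,90,5400,55,6.5,4,7,4
1,3,70,100,7000,30,8,3,9,3
1,4,70,90,6300,40,7.5,5,6.5,4
2,1,60,60,3600,40,11,4,11,5
2,2,60,60,3600,45,12.5,6,11,5.5
2,3,50,90,4500,35,5,8,6,6
2,4,60,60,3600,45,10,6,9,5
3,1,50,90,4500,55,12,10,10,7
3,2,50,60,3000,30,8,8,8,6
3,3,50,70,3500,55,10.5,7,10,7
3,4,70,40,2800,75,10,7,10,7
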