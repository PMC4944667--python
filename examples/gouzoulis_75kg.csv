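# Constant-rate literature protocol for a 75 kg subject:
# 0.3 mg/kg bolus over 30 s, then 0.02 mg/kg/min for 84 min from 1.5 min
start_min,duration_min,rate_mg_per_min,amount_mg,weight_kg
0.0,0.5,45.0,22.5,75.0
1.5,84.0,1.5,126.0,75.0
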