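# 0.4 mg/kg intravenous bolus for a 75 kg subject, infused over 30 s
start_min,duration_min,rate_mg_per_min,amount_mg,weight_kg
0.0,0.5,60.0,30.0,75.0
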