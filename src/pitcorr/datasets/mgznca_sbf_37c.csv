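time_days,mass_loss_pct
0,0
3,0.94
7,10.80
14,35.33
21,62.22
28,89.27
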