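age,annual_death_probability
60,0.00661
61,0.00728
62,0.00801
63,0.00880
64,0.00964
65,0.01057
66,0.01159
67,0.01271
68,0.01395
69,0.01532
70,0.01685
71,0.01854
72,0.02042
73,0.02253
74,0.02489
75,0.02754
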