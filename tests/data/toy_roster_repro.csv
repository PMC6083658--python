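id,state,start_date,end_date
B,infant_lt_3mo,2024-02-15,2024-03-10
C,max_tumescent,2024-02-25,2024-03-05
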