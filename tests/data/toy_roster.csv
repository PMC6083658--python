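id,sex,adult_from_date
A,m,2015-01-01
B,f,2016-01-01
C,f,2016-06-01
D,m,2017-01-01
S,f,2026-01-01
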