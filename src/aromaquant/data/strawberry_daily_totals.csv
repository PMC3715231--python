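day,total_ugm3
0,68569
1,58503
3,730593
6,382245
9,6086
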