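.v 3
# 1 = x1
# 2 = x2
# 3 = x3
.n 1 1 1
0 0
1 1
.n 2 1 1
0 0
1 1
.n 3 1 2
0 0
1 1
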