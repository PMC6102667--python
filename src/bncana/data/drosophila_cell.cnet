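.v 15
# 1 = SLP
# 2 = nWG
# 3 = nHH
# 4 = wg
# 5 = WG
# 6 = en
# 7 = EN
# 8 = hh
# 9 = HH
# 10 = ptc
# 11 = PTC
# 12 = ci
# 13 = CI
# 14 = CIA
# 15 = CIR
.n 1 1 1
0 0
1 1
.n 2 1 2
0 0
1 1
.n 3 1 3
0 0
1 1
.n 4 4 14 1 15 4
0000 0
0001 0
0010 0
0011 0
0100 0
0101 1
0110 0
0111 0
1000 0
1001 1
1010 0
1011 0
1100 1
1101 1
1110 0
1111 0
.n 5 1 4
0 0
1 1
.n 6 2 2 1
00 0
01 0
10 1
11 0
.n 7 1 6
0 0
1 1
.n 8 2 7 15
00 0
01 0
10 1
11 0
.n 9 1 8
0 0
1 1
.n 10 6 14 7 15 11 9 3
000000 0
000001 0
000010 0
000011 0
000100 1
000101 0
000110 0
000111 0
001000 0
001001 0
001010 0
001011 0
001100 1
001101 0
001110 0
001111 0
010000 0
010001 0
010010 0
010011 0
010100 1
010101 0
010110 0
010111 0
011000 0
011001 0
011010 0
011011 0
011100 1
011101 0
011110 0
011111 0
100000 1
100001 1
100010 1
100011 1
100100 1
100101 1
100110 1
100111 1
101000 0
101001 0
101010 0
101011 0
101100 1
101101 0
101110 0
101111 0
110000 0
110001 0
110010 0
110011 0
110100 1
110101 0
110110 0
110111 0
111000 0
111001 0
111010 0
111011 0
111100 1
111101 0
111110 0
111111 0
.n 11 4 10 11 9 3
0000 0
0001 0
0010 0
0011 0
0100 1
0101 0
0110 0
0111 0
1000 1
1001 1
1010 1
1011 1
1100 1
1101 1
1110 1
1111 1
.n 12 1 7
0 1
1 0
.n 13 1 12
0 0
1 1
.n 14 3 13 11 3
000 0
001 0
010 0
011 0
100 1
101 1
110 0
111 1
.n 15 3 13 11 3
000 0
001 0
010 0
011 0
100 0
101 0
110 1
111 0
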