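.v 11
# 1 = Cln3
# 2 = MBF
# 3 = SBF
# 4 = Cln12
# 5 = Cdh1
# 6 = Swi5
# 7 = Cdc20
# 8 = Clb56
# 9 = Sic1
# 10 = Clb12
# 11 = Mcm1
.n 1 0
0
.n 2 3 1 10 2
000 0
001 1
010 0
011 0
100 1
101 1
110 0
111 1
.n 3 3 1 10 3
000 0
001 1
010 0
011 0
100 1
101 1
110 0
111 1
.n 4 1 3
0 0
1 1
.n 5 5 7 4 8 10 5
00000 0
00001 1
00010 0
00011 0
00100 0
00101 0
00110 0
00111 0
01000 0
01001 0
01010 0
01011 0
01100 0
01101 0
01110 0
01111 0
10000 1
10001 1
10010 0
10011 1
10100 0
10101 1
10110 0
10111 0
11000 0
11001 1
11010 0
11011 0
11100 0
11101 0
11110 0
11111 0
.n 6 3 11 7 10
000 0
001 0
010 1
011 0
100 1
101 0
110 1
111 1
.n 7 2 10 11
00 0
01 1
10 1
11 1
.n 8 4 2 9 7 8
0000 0
0001 1
0010 0
0011 0
0100 0
0101 0
0110 0
0111 0
1000 1
1001 1
1010 0
1011 1
1100 0
1101 1
1110 0
1111 0
.n 9 6 7 6 4 8 10 9
000000 0
000001 1
000010 0
000011 0
000100 0
000101 0
000110 0
000111 0
001000 0
001001 0
001010 0
001011 0
001100 0
001101 0
001110 0
001111 0
010000 1
010001 1
010010 0
010011 1
010100 0
010101 1
010110 0
010111 0
011000 0
011001 1
011010 0
011011 0
011100 0
011101 0
011110 0
011111 0
100000 1
100001 1
100010 0
100011 1
100100 0
100101 1
100110 0
100111 0
101000 0
101001 1
101010 0
101011 0
101100 0
101101 0
101110 0
101111 0
110000 1
110001 1
110010 1
110011 1
110100 1
110101 1
110110 0
110111 1
111000 1
111001 1
111010 0
111011 1
111100 0
111101 1
111110 0
111111 0
.n 10 6 8 11 7 9 5 10
000000 0
000001 1
000010 0
000011 0
000100 0
000101 0
000110 0
000111 0
001000 0
001001 0
001010 0
001011 0
001100 0
001101 0
001110 0
001111 0
010000 1
010001 1
010010 0
010011 1
010100 0
010101 1
010110 0
010111 0
011000 0
011001 1
011010 0
011011 0
011100 0
011101 0
011110 0
011111 0
100000 1
100001 1
100010 0
100011 1
100100 0
100101 1
100110 0
100111 0
101000 0
101001 1
101010 0
101011 0
101100 0
101101 0
101110 0
101111 0
110000 1
110001 1
110010 1
110011 1
110100 1
110101 1
110110 0
110111 1
111000 1
111001 1
111010 0
111011 1
111100 0
111101 1
111110 0
111111 0
.n 11 2 8 10
00 0
01 1
10 1
11 1
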