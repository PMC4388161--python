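# synthetic stand-in: 24-vertex cubic girth-5 snark with threefold symmetry
# (|Aut| = 12, chromatic index 4); not the published Goldberg G3 embedding.
0 1
0 2
0 3
1 4
1 5
2 6
2 19
3 7
3 10
4 13
4 21
5 12
5 20
6 7
6 15
7 22
8 9
8 10
8 11
9 12
9 13
10 14
11 15
11 18
12 21
13 20
14 15
14 23
16 17
16 18
16 19
17 20
17 21
18 22
19 23
22 23
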