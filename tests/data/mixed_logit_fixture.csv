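center_id,arm,outcome
1,0,0
1,1,0
1,1,0
1,0,0
1,1,0
1,0,0
1,0,0
1,1,0
1,0,0
1,1,0
1,0,0
1,1,1
1,0,1
1,0,0
1,1,1
1,1,0
1,1,0
1,0,0
1,1,0
1,0,0
1,0,1
1,1,0
1,1,0
1,0,0
1,1,1
2,0,0
2,0,1
2,1,1
2,1,1
2,1,0
2,0,0
2,0,0
2,1,0
2,0,1
2,0,0
2,1,0
2,1,0
2,0,0
2,1,0
2,1,1
2,0,0
2,0,0
2,1,1
2,1,0
2,0,0
2,1,0
2,0,0
2,0,1
2,1,0
2,1,0
3,1,0
3,0,0
3,0,1
3,1,0
3,0,0
3,1,0
3,0,0
3,1,0
3,0,0
3,1,1
3,0,0
3,1,0
3,1,0
3,0,0
3,0,0
3,1,0
3,1,0
3,1,0
3,0,0
3,0,0
3,0,0
3,0,0
3,1,1
3,1,0
3,0,0
4,1,0
4,0,0
4,0,1
4,1,0
4,1,1
4,1,0
4,0,1
4,0,1
4,0,0
4,0,1
4,1,0
4,1,1
4,0,1
4,1,1
4,1,1
4,0,1
4,1,0
4,1,1
4,0,1
4,0,1
4,1,1
4,0,1
4,0,1
4,1,0
4,0,0
5,0,1
5,1,1
5,0,0
5,1,1
5,0,0
5,1,0
5,0,0
5,1,0
5,0,0
5,1,1
5,0,0
5,1,1
5,1,1
5,0,0
5,1,1
5,0,0
5,0,0
5,1,0
5,0,0
5,1,1
5,1,1
5,0,1
5,0,0
5,1,1
5,0,0
6,0,0
6,1,0
6,0,0
6,1,0
6,0,0
6,1,1
6,1,1
6,0,0
6,0,0
6,1,1
6,1,1
6,0,0
6,1,0
6,0,1
6,1,0
6,0,0
6,0,0
6,1,0
6,0,0
6,1,1
6,1,0
6,1,1
6,0,0
6,0,0
6,1,0
7,1,0
7,1,0
7,0,0
7,0,0
7,0,1
7,0,0
7,1,0
7,1,0
7,0,0
7,1,0
7,1,1
7,0,0
7,0,1
7,1,0
7,1,1
7,0,0
7,0,0
7,1,1
7,1,0
7,0,0
7,1,1
7,0,0
7,0,0
7,1,1
7,0,1
8,0,0
8,1,0
8,1,0
8,0,0
8,0,0
8,1,0
8,0,1
8,1,1
8,1,1
8,1,0
8,0,1
8,0,0
8,0,0
8,0,0
8,1,1
8,1,1
8,0,1
8,0,0
8,1,1
8,1,1
8,1,0
8,0,0
8,0,0
8,1,0
8,1,0
9,1,0
9,0,0
9,0,0
9,1,0
9,0,0
9,1,0
9,1,0
9,0,0
9,1,0
9,0,0
9,0,0
9,1,0
9,0,0
9,1,0
9,0,0
9,1,0
9,1,0
9,0,0
9,1,0
9,0,1
9,0,0
9,1,0
9,1,0
9,0,0
9,1,0
10,0,1
10,0,1
10,1,1
10,1,1
10,1,1
10,1,0
10,0,1
10,0,1
10,1,1
10,1,0
10,0,0
10,0,0
10,1,0
10,1,1
10,0,0
10,0,0
10,0,1
10,0,1
10,1,1
10,1,0
10,0,0
10,0,0
10,1,1
10,1,1
10,1,1
11,1,0
11,0,0
11,1,1
11,0,1
11,0,1
11,0,1
11,1,1
11,1,1
11,0,1
11,0,0
11,1,1
11,1,1
11,0,0
11,1,1
11,0,0
11,1,0
11,1,0
11,1,1
11,0,1
11,0,0
11,0,0
11,1,1
11,0,0
11,1,1
11,0,0
12,1,0
12,1,1
12,0,0
12,0,0
12,0,0
12,0,0
12,1,0
12,1,1
12,0,0
12,1,0
12,1,0
12,0,0
12,0,0
12,1,0
12,0,0
12,1,0
12,1,0
12,0,0
12,0,0
12,1,1
12,1,0
12,0,0
12,1,1
12,0,0
12,1,0
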