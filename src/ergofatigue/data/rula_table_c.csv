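score_a,score_b,grand
1,1,1
1,2,2
1,3,3
1,4,3
1,5,4
1,6,5
1,7,5
2,1,2
2,2,2
2,3,3
2,4,4
2,5,4
2,6,5
2,7,5
3,1,3
3,2,3
3,3,3
3,4,4
3,5,4
3,6,5
3,7,6
4,1,3
4,2,3
4,3,3
4,4,4
4,5,5
4,6,6
4,7,6
5,1,4
5,2,4
5,3,4
5,4,5
5,5,6
5,6,7
5,7,7
6,1,4
6,2,4
6,3,5
6,4,6
6,5,6
6,6,7
6,7,7
7,1,5
7,2,5
7,3,6
7,4,6
7,5,7
7,6,7
7,7,7
8,1,5
8,2,5
8,3,6
8,4,7
8,5,7
8,6,7
8,7,7
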