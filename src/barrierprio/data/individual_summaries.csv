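behaviour_id,barrier_id,attribute,median,iqr_low,iqr_high
1,1.1,influence,6.0,5.0,6.0
1,1.1,difficulty,2.0,1.0,2.0
1,1.2,influence,5.0,4.0,5.0
1,1.2,difficulty,3.0,2.0,4.0
1,1.3,influence,3.0,3.0,4.0
1,1.3,difficulty,3.0,3.0,4.0
1,1.4,influence,3.0,2.0,4.0
1,1.4,difficulty,4.0,3.0,5.0
1,1.5,influence,2.0,1.0,4.0
1,1.5,difficulty,5.0,2.0,6.0
1,1.6,influence,2.0,1.0,2.0
1,1.6,difficulty,5.0,4.0,6.0
2,2.1,influence,7.5,5.5,9.0
2,2.1,difficulty,3.0,2.0,4.5
2,2.2,influence,7.5,5.0,9.0
2,2.2,difficulty,4.5,2.5,7.5
2,2.3,influence,7.0,4.0,9.0
2,2.3,difficulty,2.5,1.0,6.5
2,2.4,influence,6.0,4.0,8.0
2,2.4,difficulty,4.0,2.0,6.0
2,2.5,influence,5.5,4.5,8.0
2,2.5,difficulty,7.0,5.0,8.5
2,2.6,influence,5.5,2.0,8.0
2,2.6,difficulty,5.5,3.0,7.5
2,2.7,influence,5.0,3.0,7.0
2,2.7,difficulty,6.5,2.0,7.0
2,2.8,influence,4.0,3.0,5.5
2,2.8,difficulty,5.0,4.0,8.5
2,2.9,influence,3.0,1.0,5.0
2,2.9,difficulty,6.5,5.0,8.0
3,3.1,influence,6.5,3.5,7.0
3,3.1,difficulty,2.5,2.0,5.0
3,3.2,influence,6.5,2.0,8.0
3,3.2,difficulty,4.0,1.0,7.0
3,3.3,influence,5.5,2.5,6.5
3,3.3,difficulty,3.0,2.0,5.0
3,3.4,influence,5.0,3.5,6.5
3,3.4,difficulty,3.0,1.0,5.0
3,3.5,influence,4.5,3.5,6.0
3,3.5,difficulty,4.5,3.0,5.0
3,3.6,influence,4.0,1.5,5.0
3,3.6,difficulty,6.0,4.0,8.0
3,3.7,influence,3.0,2.0,5.0
3,3.7,difficulty,6.5,5.0,8.0
3,3.8,influence,2.5,1.5,5.0
3,3.8,difficulty,6.5,5.0,7.0
4,4.1,influence,4.0,3.5,5.0
4,4.1,difficulty,3.5,2.5,5.0
4,4.2,influence,4.0,3.0,5.0
4,4.2,difficulty,1.0,1.0,2.5
4,4.3,influence,2.5,1.5,4.0
4,4.3,difficulty,2.0,2.0,4.5
4,4.4,influence,2.0,1.5,3.0
4,4.4,difficulty,3.0,2.0,4.0
4,4.5,influence,2.0,1.0,4.0
4,4.5,difficulty,4.0,3.0,5.0
5,5.1,influence,3.0,2.5,4.0
5,5.1,difficulty,3.5,1.5,4.0
5,5.2,influence,2.5,1.0,3.5
5,5.2,difficulty,3.0,1.5,4.0
5,5.3,influence,2.0,1.0,3.0
5,5.3,difficulty,1.5,1.0,2.0
5,5.4,influence,2.0,2.0,3.5
5,5.4,difficulty,2.5,2.0,3.0
6,6.1,influence,2.0,1.0,2.0
6,6.1,difficulty,2.0,1.0,2.0
6,6.2,influence,1.0,1.0,2.0
6,6.2,difficulty,1.0,1.0,2.0
7,7.1,influence,5.5,4.0,7.0
7,7.1,difficulty,3.0,1.0,4.0
7,7.2,influence,5.5,4.0,7.0
7,7.2,difficulty,3.0,1.0,3.5
7,7.3,influence,5.0,2.0,6.0
7,7.3,difficulty,6.0,4.5,6.5
7,7.4,influence,3.5,1.5,6.0
7,7.4,difficulty,3.5,2.0,4.5
7,7.5,influence,3.5,3.0,6.0
7,7.5,difficulty,3.5,2.0,5.0
7,7.6,influence,2.5,1.0,4.5
7,7.6,difficulty,5.0,4.5,6.5
7,7.7,influence,2.0,2.0,4.0
7,7.7,difficulty,5.5,3.0,7.0
8,8.1,influence,8.0,6.0,8.0
8,8.1,difficulty,2.0,1.0,2.0
8,8.2,influence,5.0,4.0,7.0
8,8.2,difficulty,2.0,2.0,3.0
8,8.3,influence,5.0,2.0,6.0
8,8.3,difficulty,4.0,3.0,6.0
8,8.4,influence,5.0,4.0,6.0
8,8.4,difficulty,5.0,5.0,7.0
8,8.5,influence,5.0,3.0,7.0
8,8.5,difficulty,4.0,2.0,5.0
8,8.6,influence,4.0,3.0,6.0
8,8.6,difficulty,5.0,3.0,6.0
8,8.7,influence,3.0,1.0,4.0
8,8.7,difficulty,7.0,4.0,8.0
8,8.8,influence,4.0,2.0,4.0
8,8.8,difficulty,7.0,6.0,8.0
9,9.1,influence,4.0,4.0,4.0
9,9.1,difficulty,1.0,1.0,1.5
9,9.2,influence,3.0,2.0,3.0
9,9.2,difficulty,2.0,1.5,2.0
9,9.3,influence,2.0,1.5,2.5
9,9.3,difficulty,3.0,2.5,3.5
9,9.4,influence,1.5,1.0,2.0
9,9.4,difficulty,4.0,3.0,4.0
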