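behaviour_id,barrier_id,influence_rank,difficulty_rank,desirability
1,1.1,6,1,desirable
1,1.2,5,3,desirable
1,1.4,3,4,desirable
1,1.6,2,6,desirable
1,1.3,4,2,least_desirable
1,1.5,1,5,least_desirable
2,2.1,9,2,desirable
2,2.5,4,8,desirable
2,2.6,6,6,desirable
2,2.2,1,4,least_desirable
2,2.3,9,1,least_desirable
2,2.4,8,2,least_desirable
2,2.7,6,5,least_desirable
2,2.8,4,6,least_desirable
2,2.9,3,8,least_desirable
3,3.2,8,3,desirable
3,3.8,3,7,desirable
3,3.1,7,2,least_desirable
3,3.3,6,3,least_desirable
3,3.4,6,1,least_desirable
3,3.5,6,3,least_desirable
3,3.6,2,6,least_desirable
3,3.7,3,6,least_desirable
4,4.1,5,4,most_desirable
4,4.2,5,1,least_desirable
4,4.3,3,2,least_desirable
4,4.4,2,3,least_desirable
4,4.5,3,4,least_desirable
5,5.1,1,4,desirable
5,5.2,3,3,desirable
5,5.3,4,1,desirable
5,5.4,2,2,least_desirable
6,6.2,2,2,most_desirable
6,6.1,1,1,least_desirable
7,7.1,7,1,desirable
7,7.2,6,2,desirable
7,7.3,5,3,desirable
7,7.4,4,5,desirable
7,7.6,2,6,desirable
7,7.7,2,6,desirable
7,7.5,4,3,least_desirable
8,8.2,8,1,desirable
8,8.4,5,6,desirable
8,8.5,6,4,desirable
8,8.8,2,8,desirable
8,8.1,5,2,least_desirable
8,8.3,5,4,least_desirable
8,8.6,3,4,least_desirable
8,8.7,2,7,least_desirable
9,9.1,4,1,desirable
9,9.2,3,2,desirable
9,9.3,2,3,desirable
9,9.4,1,4,desirable
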