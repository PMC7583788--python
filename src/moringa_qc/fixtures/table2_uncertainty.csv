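compound,medium,u_expanded
1,leaves,8.1
2,leaves,7.4
3,leaves,0.3
4,leaves,1.2
5,leaves,4.0
6,leaves,0.4
7,leaves,7.0
8,leaves,2.1
9,leaves,1.6
10,leaves,0.5
1,porridge,7.3
2,porridge,2.9
3,porridge,1.9
4,porridge,5.7
5,porridge,3.2
6,porridge,3.2
7,porridge,7.5
8,porridge,1.9
9,porridge,5.4
10,porridge,2.3
1,pill,9.3
2,pill,1.5
3,pill,0.9
4,pill,6.6
5,pill,6.0
6,pill,1.7
7,pill,0.5
8,pill,2.4
9,pill,0.4
10,pill,3.7
1,seeds,10.7
2,seeds,1.6
3,seeds,1.7
4,seeds,5.5
5,seeds,2.8
6,seeds,0.6
7,seeds,2.8
8,seeds,3.6
9,seeds,1.4
10,seeds,2.4
1,teabag,6.0
2,teabag,9.8
3,teabag,2.3
4,teabag,4.6
5,teabag,3.8
6,teabag,3.3
7,teabag,3.9
8,teabag,1.5
9,teabag,4.1
10,teabag,4.1
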