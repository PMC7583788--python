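compound,medium,slope,intercept,r_squared,lod,loq
1,solvent,5.6426,0.1675,0.9992,0.4,1.5
1,leaves,6.4329,0.3185,0.9920,1.4,4.7
1,porridge,8.1535,8.0563,0.9926,1.4,4.5
1,pill,7.1004,4.761,0.9929,1.3,4.4
1,seeds,7.1488,1.322,0.9946,1.4,4.6
1,teabag,4.0215,2.1731,0.9914,0.8,2.6
2,solvent,5.2976,1.7616,0.9983,0.2,0.8
2,leaves,6.5537,0.3585,0.9917,0.9,2.8
2,porridge,4.5566,0.0311,0.9980,0.6,2.1
2,pill,6.304,-0.1218,0.9998,0.4,1.2
2,seeds,5.5164,-1.0216,0.9977,0.8,2.5
2,teabag,5.655,0.0956,0.9910,1.5,2.9
3,solvent,3.5287,0.0056,0.9997,0.2,0.6
3,leaves,4.4315,-0.1674,0.9918,1.4,4.8
3,porridge,4.2137,-0.7968,0.9978,0.7,2.5
3,pill,4.6886,-0.0703,0.9998,0.2,0.8
3,seeds,4.2517,-0.9134,0.9972,0.8,2.8
3,teabag,4.4485,-1.2286,0.9953,0.9,3.6
4,solvent,17.023,0.2835,0.9989,0.1,0.2
4,leaves,16.614,1.8819,0.9900,0.5,1.8
4,porridge,15.178,1.3813,0.9944,0.2,0.8
4,pill,19.759,-0.7674,0.9942,1.2,4.1
4,seeds,14.183,-0.8676,0.9957,0.3,1.0
4,teabag,14.365,0.2648,0.9928,0.1,0.4
5,solvent,6.7695,2.3567,0.9998,0.2,0.6
5,leaves,7.5045,0.1158,0.9930,0.5,1.5
5,porridge,7.9884,-1.3053,0.9983,0.6,2.1
5,pill,8.2307,0.2162,0.9954,1.1,3.6
5,seeds,7.7802,-0.1998,0.9997,0.3,0.9
5,teabag,8.256,-2.4614,0.9907,1.5,2.9
6,solvent,6.7935,0.0046,0.9990,0.4,1.2
6,leaves,5.6243,-0.0925,0.9910,0.5,1.5
6,porridge,5.5703,0.016,0.9978,0.5,1.6
6,pill,7.3807,-0.9386,0.9991,0.5,1.6
6,seeds,5.5648,3.842,0.9978,0.4,1.2
6,teabag,7.3829,-1.2771,0.9980,0.7,2.3
7,solvent,1.1315,-0.0233,0.9970,0.6,2.0
7,leaves,0.9576,0.9475,0.9995,0.9,3.1
7,porridge,0.8799,0.8954,0.9961,1.3,4.2
7,pill,1.2452,-0.1016,0.9992,0.9,3.0
7,seeds,0.9489,12.643,0.9998,0.6,2.1
7,teabag,1.2494,-0.2026,0.9982,0.7,2.2
8,solvent,14.335,-0.7785,0.9999,0.1,0.4
8,leaves,10.429,-0.3695,0.9905,0.2,3.1
8,porridge,17.239,-3.9107,0.9966,0.9,0.4
8,pill,10.303,0.137,0.9978,0.7,2.5
8,seeds,16.972,-4.5354,0.9955,1.1,3.5
8,teabag,12.86,-2.3863,0.9915,1.1,3.7
9,solvent,6.8643,-0.7974,0.9952,0.8,2.8
9,leaves,5.629,0.0298,0.9919,0.9,3.3
9,porridge,4.909,-1.1473,0.9955,1.1,3.1
9,pill,6.0233,-0.1356,0.9969,0.9,2.9
9,seeds,5.7694,-0.2297,0.9966,0.9,3.0
9,teabag,7.4052,-2.0624,0.9941,1.2,4.0
10,solvent,10.077,-0.784,0.9990,0.4,1.2
10,leaves,12.112,-0.9891,0.9900,0.5,1.7
10,porridge,11.679,-2.3922,0.9974,0.8,2.7
10,pill,12.11,-1.6105,0.9989,0.5,1.7
10,seeds,11.615,-2.5661,0.9969,0.9,3.0
10,teabag,12.44,-2.7397,0.9964,0.9,3.1
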