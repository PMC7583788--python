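compound,medium,level,recovery,rsd_intra,rsd_inter
1,solvent,1,,1.1,1.6
2,solvent,1,,0.9,1.0
3,solvent,1,,0.8,0.3
4,solvent,1,,0.4,0.4
5,solvent,1,,0.7,1.1
6,solvent,1,,0.8,0.4
7,solvent,1,,1.0,0.6
8,solvent,1,,0.3,1.1
9,solvent,1,,0.9,1.6
10,solvent,1,,0.8,0.2
1,solvent,3,,0.4,0.5
2,solvent,3,,0.7,0.05
3,solvent,3,,0.6,0.3
4,solvent,3,,0.4,0.05
5,solvent,3,,0.4,0.3
6,solvent,3,,0.6,0.1
7,solvent,3,,0.4,0.6
8,solvent,3,,0.8,0.05
9,solvent,3,,0.2,0.08
10,solvent,3,,0.5,0.1
1,solvent,10,,0.3,0.02
2,solvent,10,,0.2,0.03
3,solvent,10,,0.3,0.1
4,solvent,10,,0.4,0.03
5,solvent,10,,0.2,0.1
6,solvent,10,,0.2,0.05
7,solvent,10,,0.3,0.2
8,solvent,10,,0.2,0.05
9,solvent,10,,0.2,0.2
10,solvent,10,,0.2,0.05
1,leaves,3,76.0,4.3,6.3
2,leaves,3,77.4,3.2,3.5
3,leaves,3,99.8,0.4,1.5
4,leaves,3,96.5,1.6,4.2
5,leaves,3,113.0,0.9,2.8
6,leaves,3,100.0,1.6,3.2
7,leaves,3,75.7,1.8,4.0
8,leaves,3,93.9,1.5,3.0
9,leaves,3,94.0,1.9,3.5
10,leaves,3,101.4,0.8,1.6
1,leaves,6,89.5,1.8,2.5
2,leaves,6,91.6,0.8,2.3
3,leaves,6,100.5,0.6,1.2
4,leaves,6,93.7,1.3,0.9
5,leaves,6,104.7,1.0,0.6
6,leaves,6,99.6,1.7,0.3
7,leaves,6,84.8,1.6,1.8
8,leaves,6,100.3,0.9,0.2
9,leaves,6,100.0,1.5,0.4
10,leaves,6,100.4,0.4,0.4
1,leaves,10,99.1,0.4,0.3
2,leaves,10,95.6,0.6,0.4
3,leaves,10,100.5,0.4,0.6
4,leaves,10,98.2,1.2,0.6
5,leaves,10,97.3,0.3,0.5
6,leaves,10,100.5,0.4,0.2
7,leaves,10,91.1,0.5,0.6
8,leaves,10,99.9,0.3,0.6
9,leaves,10,99.9,0.6,0.2
10,leaves,10,99.5,0.4,0.2
1,porridge,3,75.9,2.3,4.0
2,porridge,3,98.5,0.6,2.5
3,porridge,3,94.3,0.5,0.9
4,porridge,3,93.7,1.9,2.8
5,porridge,3,100.6,1.2,2.9
6,porridge,3,99.2,0.5,0.7
7,porridge,3,75.8,1.6,4.6
8,porridge,3,94.0,0.8,0.3
9,porridge,3,82.0,1.7,1.5
10,porridge,3,94.0,0.2,1.4
1,porridge,6,87.5,0.4,1.6
2,porridge,6,101.6,0.5,1.0
3,porridge,6,97.0,0.6,1.0
4,porridge,6,96.4,1.3,3.6
5,porridge,6,101.0,0.2,4.7
6,porridge,6,100.8,0.5,1.2
7,porridge,6,90.9,1.0,4.9
8,porridge,6,96.0,0.2,1.9
9,porridge,6,91.33,0.3,0.2
10,porridge,6,96.8,0.5,0.9
1,porridge,10,99.4,0.7,0.3
2,porridge,10,99.6,0.6,0.5
3,porridge,10,100.6,0.2,0.2
4,porridge,10,99.9,1.2,4.6
5,porridge,10,99.6,0.3,1.2
6,porridge,10,99.8,0.3,0.2
7,porridge,10,98.9,1.0,2.6
8,porridge,10,102.0,0.6,0.3
9,porridge,10,99.4,0.7,0.3
10,porridge,10,101.7,0.2,0.4
1,pill,3,72.0,1.7,4.4
2,pill,3,99.3,0.5,1.4
3,pill,3,97.7,1.4,0.5
4,pill,3,78.0,2.0,1.7
5,pill,3,82.0,2.9,1.0
6,pill,3,94.3,1.0,0.3
7,pill,3,99.3,1.6,3.0
8,pill,3,100.2,0.8,2.4
9,pill,3,99.3,0.6,0.3
10,pill,3,87.3,1.4,0.4
1,pill,6,93.0,1.1,0.2
2,pill,6,99.8,0.8,0.2
3,pill,6,101.3,0.6,0.5
4,pill,6,90.5,1.8,0.6
5,pill,6,91.33,0.4,0.1
6,pill,6,99.7,1.2,0.3
7,pill,6,97.3,1.4,1.8
8,pill,6,100.0,0.4,1.6
9,pill,6,99.7,0.6,2.2
10,pill,6,98.0,0.8,0.7
1,pill,10,98.2,0.1,0.4
2,pill,10,100.1,0.8,0.6
3,pill,10,99.7,0.3,0.4
4,pill,10,99.1,1.0,0.3
5,pill,10,99.4,0.4,0.2
6,pill,10,100.6,0.6,0.2
7,pill,10,101.0,1.4,0.5
8,pill,10,99.8,0.3,0.2
9,pill,10,100.3,0.5,0.2
10,pill,10,101.1,0.2,0.7
1,seeds,3,66.7,4.7,6.0
2,seeds,3,95.3,0.6,0.6
3,seeds,3,93.7,0.8,0.8
4,seeds,3,96.0,1.8,4.1
5,seeds,3,97.0,1.0,2.4
6,seeds,3,100.0,0.4,0.5
7,seeds,3,108.9,0.7,0.7
8,seeds,3,92.3,0.6,2.8
9,seeds,3,98.4,0.4,0.6
10,seeds,3,93.7,1.3,1.4
1,seeds,6,84.2,0.3,0.2
2,seeds,6,96.5,0.2,0.5
3,seeds,6,96.7,0.4,0.6
4,seeds,6,100.8,1.7,4.4
5,seeds,6,101.3,0.3,0.5
6,seeds,6,100.6,0.2,0.8
7,seeds,6,105.4,0.6,0.2
8,seeds,6,95.5,0.2,0.5
9,seeds,6,99.7,0.4,0.5
10,seeds,6,96.3,0.3,0.3
1,seeds,10,99.0,0.2,0.2
2,seeds,10,101.7,0.3,0.3
3,seeds,10,101.8,0.3,1.2
4,seeds,10,100.0,1.4,3.5
5,seeds,10,99.7,0.3,1.3
6,seeds,10,99.9,0.3,0.4
7,seeds,10,100.1,0.3,0.8
8,seeds,10,102.3,0.1,0.2
9,seeds,10,100.2,0.3,1.2
10,seeds,10,101.9,0.2,0.5
1,teabag,3,86.2,4.3,6.3
2,teabag,3,69.7,4.5,5.7
3,teabag,3,93.7,2.0,1.1
4,teabag,3,99.2,2.0,3.5
5,teabag,3,96.3,1.3,2.6
6,teabag,3,95.3,1.4,2.7
7,teabag,3,96.0,1.9,2.0
8,teabag,3,98.9,1.5,1.2
9,teabag,3,93.7,1.9,3.6
10,teabag,3,94.7,1.2,3.7
1,teabag,6,94.1,3.2,3.2
2,teabag,6,91.0,3.1,3.5
3,teabag,6,95.7,0.5,0.5
4,teabag,6,97.8,0.5,3.3
5,teabag,6,91.2,0.5,0.6
6,teabag,6,97.0,0.9,0.7
7,teabag,6,96.8,1.3,3.7
8,teabag,6,93.2,0.3,1.2
9,teabag,6,93.8,0.3,0.5
10,teabag,6,95.3,1.2,1.6
1,teabag,10,103.6,0.4,0.6
2,teabag,10,98.2,0.1,0.5
3,teabag,10,102.3,0.6,0.5
4,teabag,10,100.3,0.6,2.9
5,teabag,10,103.6,0.7,2.3
6,teabag,10,101.5,0.1,1.4
7,teabag,10,101.5,1.3,3.1
8,teabag,10,102.6,0.2,0.3
9,teabag,10,102.8,0.3,0.8
10,teabag,10,102.1,0.4,0.9
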