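sample,product_type,region,c1,c2,c3,c4,c5,c6,c7,c8,c9,c10
L1,leaves,Mpumalanga (SA),0.0,0.1,6.9,0.1,0.1,6.9,7.4,9.4,0.0,5.6
L2,leaves,Mpumalanga (SA),0.0,0.0,6.1,0.0,0.1,8.7,7.0,7.0,0.0,7.9
L3,leaves,Mpumalanga (SA),0.0,0.0,5.9,0.0,0.1,9.7,7.5,7.0,0.0,6.5
L4,leaves,Mpumalanga (SA),0.1,0.1,8.4,0.1,0.1,5.0,7.5,8.6,0.1,6.6
L5,leaves,Limpopo (SA),0.0,0.1,5.0,0.0,0.0,6.5,6.4,0.0,0.0,5.9
L6,leaves,Limpopo (SA),0.1,0.1,5.0,0.0,0.1,8.8,5.0,0.1,0.0,6.9
L7,leaves,Limpopo (SA),0.0,0.1,6.4,0.0,0.0,5.2,8.9,0.0,0.0,7.4
L8,leaves,Limpopo (SA),0.0,0.1,6.1,0.0,5.4,7.0,8.0,0.0,0.0,7.1
L9,leaves,Ethiopia,0.0,0.0,5.8,0.0,0.1,4.2,7.1,0.1,0.0,0.1
P1,pill,MI (SA),0.0,0.1,5.6,0.0,0.0,4.5,6.6,0.1,0.0,5.7
P2,pill,MI (SA),0.0,0.1,5.2,0.0,0.1,5.1,6.9,0.1,0.0,6.0
P3,pill,MII (SA),0.0,0.1,6.9,0.0,5.0,6.2,8.6,0.0,0.0,7.7
P4,pill,MII (SA),0.1,0.1,5.7,0.0,0.1,6.7,0.1,0.1,0.0,7.6
P5,pill,MIII (SA),0.1,6.0,0.0,0.0,5.9,5.0,7.3,0.1,0.0,5.8
P6,pill,MIII (SA),0.1,5.7,0.0,0.0,5.6,6.1,8.5,0.1,0.0,5.2
PRD1,porridge,MI (SA),0.1,0.0,6.0,0.1,5.8,6.0,9.6,4.5,0.0,0.1
PRD2,porridge,MI (SA),0.1,0.0,5.9,0.1,6.0,6.0,9.1,4.5,0.0,0.1
PRD3,porridge,MIV (SA),6.9,0.0,8.0,5.1,6.9,6.8,0.1,0.0,0.0,9.3
PRD4,porridge,MIV (SA),5.3,0.0,7.6,5.0,6.5,5.8,0.1,0.0,0.0,8.8
TB1,teabag,MI (SA),0.0,0.1,6.6,0.0,0.0,7.0,7.2,5.8,0.0,0.0
TB2,teabag,MI (SA),0.1,0.0,6.4,0.0,0.0,4.2,6.5,4.6,0.0,0.0
TB3,teabag,MII (SA),0.0,0.0,8.2,5.0,0.0,6.1,8.0,6.2,0.0,0.0
TB4,teabag,MII (SA),0.1,0.0,8.1,6.8,0.0,7.0,8.1,5.9,0.0,0.0
TB5,teabag,MIV (SA),0.0,5.6,5.0,0.0,0.0,4.1,6.9,4.2,0.0,0.1
TB6,teabag,MIV (SA),0.0,6.2,6.0,0.0,0.0,4.2,6.6,4.6,0.0,0.1
TB7,teabag,Jamaica,6.5,0.0,6.3,0.1,8.7,8.5,7.0,4.7,0.0,6.1
S1,seeds,Mpumalanga (SA),6.4,4.7,0.0,0.0,0.1,6.5,9.6,0.0,4.7,0.0
S2,seeds,Mpumalanga (SA),5.2,0.1,0.1,0.0,0.1,7.7,8.8,0.0,0.1,0.1
S3,seeds,Mpumalanga (SA),5.6,0.1,0.1,0.0,0.1,5.1,8.1,0.0,0.1,0.0
S4,seeds,Limpopo (SA),5.0,4.7,0.1,0.0,0.1,5.5,9.5,0.0,4.9,0.1
S5,seeds,Limpopo (SA),9.4,4.6,0.0,0.0,0.1,5.1,6.7,0.0,0.0,0.1
S6,seeds,Zambia,0.0,5.8,0.1,0.0,6.9,5.4,0.1,0.0,5.6,0.0
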