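run_id,batch_id,X1,X2,X3,X4,X5,X6,X7,X8,X9,X10
1,PN12,85,10.0,1000,200,500,2.0,2.0,3.0,65,180
2,PN7,85,6.0,600,100,300,1.0,1.0,1.0,55,120
3,PN10,90,8.0,1000,100,500,2.0,1.0,1.0,55,120
4,PN2,80,8.0,600,200,300,1.0,2.0,3.0,65,180
5,PN15,90,10.0,800,200,300,2.0,2.0,1.0,55,120
6,PN3,80,6.0,800,100,500,1.0,1.0,3.0,65,180
7,PN11,90,6.0,1000,150,500,1.0,2.0,3.0,55,120
8,PN10,80,10.0,600,150,300,2.0,1.0,1.0,65,180
9,PN8,90,10.0,600,200,400,2.0,1.0,3.0,65,120
10,PN11,80,6.0,1000,100,400,1.0,2.0,1.0,55,180
11,PN12,90,10.0,1000,100,500,1.5,2.0,1.0,65,180
12,PN14,80,6.0,600,200,300,1.5,1.0,3.0,55,120
13,PN4,90,6.0,1000,200,300,2.0,1.5,3.0,55,180
14,PN9,80,10.0,600,100,500,1.0,1.5,1.0,65,120
15,PN6,90,6.0,600,200,500,1.0,2.0,2.0,65,120
16,PN8,80,10.0,1000,100,300,2.0,1.0,2.0,55,180
17,PN2,90,6.0,600,100,500,2.0,1.0,3.0,60,180
18,PN16,80,10.0,1000,200,300,1.0,2.0,1.0,60,120
19,PN5,90,6.0,600,100,300,2.0,2.0,1.0,65,150
20,PN6,80,10.0,1000,200,500,1.0,1.0,3.0,55,150
21,PN1,90,10.0,600,100,300,1.0,2.0,3.0,55,180
22,PN4,80,6.0,1000,200,500,2.0,1.0,1.0,65,120
23,PN16,90,10.0,1000,100,300,1.0,1.0,3.0,65,120
24,PN15,80,6.0,600,200,500,2.0,2.0,1.0,55,180
25,PN13,90,6.0,1000,200,300,1.0,1.0,1.0,65,180
26,PN7,80,10.0,600,100,500,2.0,2.0,3.0,55,120
27,PN3,90,10.0,600,200,500,1.0,1.0,1.0,55,180
28,PN13,80,6.0,1000,100,300,2.0,2.0,3.0,65,120
29,PN9,85,8.0,800,150,400,1.5,1.5,2.0,60,150
30,PN14,85,8.0,800,150,400,1.5,1.5,2.0,60,150
31,PN5,85,8.0,800,150,400,1.5,1.5,2.0,60,150
32,PN1,85,8.0,800,150,400,1.5,1.5,2.0,60,150
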