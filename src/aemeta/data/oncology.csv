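trial,arm,n,y,z,m,tau,historical
1,1,400,5,65,0,30,False
1,0,370,2,115,0,20,False
2,1,680,16,150,0,65,False
2,0,500,5,90,0,65,False
3,1,245,0,220,0,30,False
3,0,240,1,220,0,30,False
4,1,190,0,180,0,15,False
4,0,175,1,165,0,15,False
5,1,350,15,270,0,35,False
5,0,350,6,330,0,35,False
6,1,440,31,215,0,25,False
6,0,440,8,280,0,20,False
7,1,190,4,180,0,25,False
7,0,180,1,180,0,25,False
8,1,330,5,180,0,25,False
8,0,340,6,165,0,25,False
9,1,350,8,120,0,10,False
9,0,350,5,110,0,10,False
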