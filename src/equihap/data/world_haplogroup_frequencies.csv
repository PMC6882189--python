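code,region,subregion,n,D,I,EFG,H,L,M,N,OP,Q,R
YL,NEA,NWC,13,0,15.4,7.7,0,15.4,0,0,23.0,38.5,0
KZK,NEA,NWC,43,4.7,2.3,20.9,2.3,16.3,9.3,11.6,4.7,20.9,7.0
YQ,NEA,NWC,22,4.5,9.2,22.7,4.5,13.6,4.5,9.2,18.2,13.6,0
BLK,NEA,NWC,50,8.0,2.0,2.0,6.0,30.0,14.0,4.0,8.0,26.0,0
CDM,NEA,NWC,24,20.8,0,8.3,0,25.0,0,4.2,4.2,37.5,0
DT,NEA,NWC,30,16.7,3.3,13.3,6.7,23.3,3.4,13.3,0,16.7,3.3
DLH,NEA,NWC,13,15.4,7.7,38.5,0,23.0,0,0,0,15.4,0
MG,NEA,MG,50,0,8.0,14.0,0,14.0,6.0,12.0,16.0,28.0,2.0
IMG,NEA,NC,76,1.3,5.3,18.4,1.3,19.7,3.9,6.6,21.1,21.1,1.3
WSE,NEA,NC,12,0,0,16.7,0,16.7,0,0,16.7,50.0,0
SS,NEA,NC,13,0,0,30.7,0,15.4,15.4,0,23.1,15.4,0
WZMQ,NEA,NC,15,0,0,26.7,0,20.0,0,0,33.3,20.0,0
XNH,NEA,NC,30,3.3,10.0,3.3,0,26.7,6.7,6.7,16.6,20.0,6.7
BR,NEA,NC,1,0,0,0,0,100.0,0,0,0,0,0
SH,NEA,NC,12,8.3,16.7,8.3,0,16.7,8.3,0,0,33.4,8.3
ELC,NEA,NEC,29,24.1,3.4,10.4,0,24.1,7.0,3.4,3.4,20.8,3.4
HH,NEA,NEC,17,0,11.8,29.4,0,17.6,11.8,0,11.8,17.6,0
JL,NEA,NEC,25,12.0,8.0,8.0,8.0,12.0,0,4.0,24.0,20.0,4.0
KJU,NEA,FE,25,12.0,24.0,12.0,4.0,0,0,8.0,20.0,20.0,0
JAN,NEA,FE,9,11.1,11.1,22.2,0,11.1,0,11.1,0,33.4,0
GS,SEA,CC,6,0,0,0,0,50.0,0,0,0,33.3,16.7
SXNQ,SEA,CC,14,0,7.1,14.3,0,14.3,0,0,14.3,50.0,0
SXGZ,SEA,CC,70,0,0,8.5,0,34.3,28.6,0,28.6,0,0
HBL,SEA,CC,14,0,0,7.1,0,35.8,28.6,7.1,0,0,21.4
JZI,SEA,WC,17,11.8,5.9,11.8,0,23.5,11.8,0,0,35.2,0
LKZ,SEA,WC,10,0,0,30.0,0,50.0,10.0,0,0,10.0,0
NIM,SEA,WC,13,30.8,0,7.7,0,7.7,7.7,0,7.7,30.8,7.7
TB,SEA,WC,18,22.2,0,33.3,0,27.8,0,0,0,16.7,0
YS,SEA,WC,7,0,28.6,0,0,57.1,0,0,0,14.3,0
HQ,SEA,WC,33,6.0,3.0,9.1,3.0,42.4,6.1,0.0,6.1,18.2,6.1
SCT,SEA,SWC,3,0,0,0,0,66.7,0,0,0,33.3,0
YNT,SEA,SWC,6,0,0,16.7,0,66.6,0,16.7,0,0,0
ZD,SEA,SWC,22,9.1,4.6,13.6,9.1,31.8,22.7,0,0,9.1,0
LJ,SEA,SWC,16,25.0,6.3,12.5,12.5,37.4,0,0,6.3,0,0
LH,SEA,SWC,4,0,0,0,50.0,25.0,25.0,0,0,0,0
JC,SEA,SWC,33,9.1,3.0,6.1,6.1,24.1,18.2,6.1,18.2,9.1,0
TC,SEA,SWC,17,0,0,17.6,0,35.3,5.9,0,11.8,29.4,0
DAL,SEA,SWC,23,8.7,0,13.0,0,34.9,13.0,0,4.4,13.0,13.0
WM,SEA,SWC,17,5.9,0,11.8,0,52.9,5.8,0,0,17.7,5.9
GZ,SEA,SWC,73,6.8,6.8,5.6,8.2,32.9,6.8,0,4.1,20.6,8.2
LP,SEA,SWC,12,8.3,0,41.7,33.4,0,0,0,0,8.3,8.3
DB,SEA,SWC,19,0,0,15.8,0,52.6,15.8,0,0,5.3,10.5
WSA,SEA,SWC,42,4.8,2.4,2.4,14.3,38.0,9.5,0,7.1,4.8,16.7
YNP,SEA,SWC,16,0,0,62.5,0,31.2,0,0,6.3,0,0
MAG,SEA,SWC,4,0,0,0,0,25.0,25.0,0,0,50.0,0
MLP,SEA,SWC,8,0,0,12.5,0,12.5,12.5,0,25.0,0,37.5
BIS,SEA,SWC,22,18.2,0,13.6,4.6,18.2,9.1,0,0,13.6,22.7
SA,SA,SA,12,8.3,16.7,8.3,33.3,25.0,0,0,0,8.3,0
CA,CA,CA,48,12.5,18.8,0,8.3,20.8,14.6,0,2.1,20.8,2.1
NA,NA,NA,38,0,21.1,2.6,10.5,34.2,2.6,2.6,15.8,7.9,2.6
WA,WA,WA,170,1.2,14.1,0.6,13.5,33.5,6.5,7.1,10.0,12.4,1.2
EE,EE,EE,23,13.0,17.4,0,26.1,8.7,13.0,13.0,8.7,0,0
SE,SE,SE,366,1.1,20.5,2.5,7.1,44.5,3.0,10.7,2.5,6.0,2.2
CE,CE,CE,129,0.8,10.9,0.8,9.3,40.3,4.7,7.0,7.0,3.1,16.3
NE,NE,NE,51,11.8,9.8,0,9.8,11.8,23.5,13.7,5.9,13.7,0
WE,WE,WE,436,11.0,6.9,2.1,14.0,40.8,13.5,8.3,0,3.2,0.2
AF,AF,AF,25,0,4.0,0,4.0,88.0,0,0,4.0,0,0
NAM,NAM,NAM,86,0,7.0,0,0,82.6,3.5,5.8,0,1.2,0
SAM,SAM,SAM,54,0,5.6,0,9.3,55.6,7.4,16.7,1.9,3.7,0
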