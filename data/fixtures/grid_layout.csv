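# fadseed schema=grid_layout version=1
row,col,category
0,0,unspotted
0,1,spotted
0,2,unspotted
0,3,spotted
0,4,unspotted
0,5,spotted
0,6,unspotted
0,7,spotted
1,0,spotted
1,1,unspotted
1,2,spotted
1,3,unspotted
1,4,spotted
1,5,unspotted
1,6,spotted
1,7,unspotted
2,0,unspotted
2,1,spotted
2,2,unspotted
2,3,spotted
2,4,unspotted
2,5,spotted
2,6,unspotted
2,7,spotted
3,0,spotted
3,1,unspotted
3,2,spotted
3,3,unspotted
3,4,spotted
3,5,unspotted
3,6,spotted
3,7,unspotted
4,0,unspotted
4,1,spotted
4,2,unspotted
4,3,spotted
4,4,unspotted
4,5,spotted
4,6,unspotted
4,7,spotted
5,0,spotted
5,1,unspotted
5,2,spotted
5,3,unspotted
5,4,spotted
5,5,unspotted
5,6,spotted
5,7,unspotted
6,0,unspotted
6,1,spotted
6,2,unspotted
6,3,spotted
6,4,unspotted
6,5,spotted
6,6,unspotted
6,7,spotted
7,0,spotted
7,1,unspotted
7,2,spotted
7,3,unspotted
7,4,spotted
7,5,unspotted
7,6,spotted
7,7,unspotted
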