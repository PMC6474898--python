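# fadseed schema=grid_events version=1
event_index,time,row,col,category
1,1.0,0,0,unspotted
2,2.0,0,2,unspotted
3,3.0,0,1,spotted
4,4.0,0,4,unspotted
5,5.0,0,6,unspotted
6,6.0,1,1,unspotted
7,7.0,0,3,spotted
8,8.0,1,3,unspotted
9,9.0,1,5,unspotted
10,10.0,1,7,unspotted
11,11.0,0,5,spotted
12,12.0,2,0,unspotted
13,13.0,2,2,unspotted
14,14.0,2,4,unspotted
15,15.0,0,7,spotted
16,16.0,2,6,unspotted
17,17.0,3,1,unspotted
18,18.0,3,3,unspotted
19,19.0,1,0,spotted
20,20.0,3,5,unspotted
21,21.0,3,7,unspotted
22,22.0,4,0,unspotted
23,23.0,1,2,spotted
24,24.0,4,2,unspotted
25,25.0,4,4,unspotted
26,26.0,4,6,unspotted
27,27.0,1,4,spotted
28,28.0,5,1,unspotted
29,29.0,5,3,unspotted
30,30.0,5,5,unspotted
31,31.0,1,6,spotted
32,32.0,5,7,unspotted
33,33.0,2,1,spotted
34,34.0,6,0,unspotted
35,35.0,2,3,spotted
36,36.0,2,5,spotted
37,37.0,2,7,spotted
38,38.0,6,2,unspotted
39,39.0,3,0,spotted
40,40.0,3,2,spotted
41,41.0,3,4,spotted
42,42.0,6,4,unspotted
43,43.0,3,6,spotted
44,44.0,4,1,spotted
45,45.0,4,3,spotted
46,46.0,6,6,unspotted
47,47.0,4,5,spotted
48,48.0,4,7,spotted
49,49.0,5,0,spotted
50,50.0,7,1,unspotted
51,51.0,5,2,spotted
52,52.0,5,4,spotted
53,53.0,5,6,spotted
54,54.0,7,3,unspotted
55,55.0,6,1,spotted
56,56.0,6,3,spotted
57,57.0,6,5,spotted
58,58.0,7,5,unspotted
59,59.0,6,7,spotted
60,60.0,7,0,spotted
61,61.0,7,2,spotted
62,62.0,7,7,unspotted
63,63.0,7,4,spotted
64,64.0,7,6,spotted
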