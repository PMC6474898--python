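# fadseed schema=trials version=1
trial_id,session,time,removed_category
0,day_1,0,unspotted
1,day_1,1,spotted
2,day_1,2,unspotted
3,day_1,3,spotted
4,day_1,4,unspotted
5,day_1,5,unspotted
6,day_1,6,spotted
7,day_1,7,unspotted
8,day_1,8,spotted
9,day_1,9,unspotted
10,day_1,10,unspotted
11,day_1,11,spotted
12,day_1,12,unspotted
13,day_1,13,unspotted
14,day_1,14,spotted
15,day_1,15,unspotted
16,day_1,16,spotted
17,day_1,17,unspotted
18,day_1,18,unspotted
19,day_1,19,spotted
20,day_1,20,unspotted
21,day_1,21,spotted
22,day_1,22,unspotted
23,day_1,23,unspotted
24,day_1,24,spotted
25,day_1,25,unspotted
26,day_1,26,spotted
27,day_1,27,unspotted
28,day_1,28,unspotted
29,day_1,29,spotted
30,day_2,30,unspotted
31,day_2,31,spotted
32,day_2,32,unspotted
33,day_2,33,unspotted
34,day_2,34,spotted
35,day_2,35,unspotted
36,day_2,36,unspotted
37,day_2,37,spotted
38,day_2,38,unspotted
39,day_2,39,spotted
40,day_2,40,unspotted
41,day_2,41,unspotted
42,day_2,42,spotted
43,day_2,43,unspotted
44,day_2,44,spotted
45,day_3,45,unspotted
46,day_3,46,unspotted
47,day_3,47,spotted
48,day_3,48,unspotted
49,day_3,49,spotted
50,day_3,50,unspotted
51,day_3,51,unspotted
52,day_3,52,spotted
53,day_3,53,unspotted
54,day_3,54,spotted
55,day_3,55,unspotted
56,day_3,56,unspotted
57,day_3,57,spotted
58,day_3,58,unspotted
59,day_3,59,unspotted
60,day_3,60,spotted
61,day_3,61,unspotted
62,day_3,62,spotted
63,day_3,63,unspotted
64,day_3,64,unspotted
65,day_3,65,spotted
66,day_3,66,unspotted
67,day_3,67,spotted
68,day_3,68,unspotted
69,day_3,69,unspotted
70,day_3,70,spotted
71,day_3,71,unspotted
72,day_3,72,spotted
73,day_3,73,unspotted
74,day_3,74,unspotted
75,day_3,75,spotted
76,day_3,76,unspotted
77,day_3,77,spotted
78,day_3,78,unspotted
79,day_3,79,unspotted
80,day_3,80,spotted
81,day_3,81,unspotted
82,day_3,82,unspotted
83,day_3,83,spotted
84,day_3,84,unspotted
85,day_3,85,spotted
86,day_3,86,unspotted
87,day_3,87,unspotted
88,day_3,88,spotted
89,day_3,89,unspotted
90,day_3,90,spotted
91,day_3,91,unspotted
92,day_3,92,unspotted
93,day_3,93,spotted
94,day_3,94,unspotted
95,day_3,95,spotted
96,day_3,96,unspotted
97,day_3,97,unspotted
98,day_3,98,spotted
99,day_3,99,unspotted
100,day_3,100,spotted
101,day_3,101,unspotted
102,day_3,102,unspotted
103,day_3,103,spotted
104,day_3,104,unspotted
105,day_3,105,unspotted
106,day_3,106,spotted
107,day_3,107,unspotted
108,day_3,108,spotted
109,day_3,109,unspotted
110,day_3,110,unspotted
111,day_3,111,spotted
112,day_3,112,unspotted
113,day_3,113,spotted
114,day_3,114,unspotted
115,day_3,115,unspotted
116,day_3,116,spotted
117,day_3,117,unspotted
118,day_3,118,spotted
119,day_3,119,unspotted
120,day_3,120,unspotted
121,day_3,121,spotted
122,day_3,122,unspotted
123,day_3,123,spotted
124,day_3,124,unspotted
125,day_3,125,unspotted
126,day_3,126,spotted
127,day_3,127,unspotted
128,day_3,128,spotted
129,day_3,129,unspotted
130,day_3,130,unspotted
131,day_3,131,spotted
132,day_3,132,unspotted
133,day_3,133,unspotted
134,day_3,134,spotted
135,day_3,135,unspotted
136,day_3,136,spotted
137,day_3,137,unspotted
138,day_3,138,unspotted
139,day_3,139,spotted
140,day_3,140,unspotted
141,day_3,141,spotted
142,day_3,142,unspotted
143,day_3,143,unspotted
144,day_3,144,spotted
145,day_3,145,unspotted
146,day_3,146,spotted
147,day_3,147,unspotted
148,day_3,148,unspotted
149,day_3,149,spotted
150,day_3,150,unspotted
151,day_3,151,spotted
152,day_3,152,unspotted
153,day_3,153,unspotted
154,day_3,154,spotted
155,day_3,155,unspotted
156,day_3,156,unspotted
157,day_3,157,spotted
158,day_3,158,unspotted
159,day_3,159,spotted
160,day_3,160,unspotted
161,day_3,161,unspotted
162,day_3,162,spotted
163,day_3,163,unspotted
164,day_3,164,spotted
165,day_3,165,unspotted
166,day_3,166,unspotted
167,day_3,167,spotted
168,day_3,168,unspotted
169,day_3,169,spotted
170,day_3,170,unspotted
171,day_3,171,unspotted
172,day_3,172,spotted
173,day_3,173,unspotted
174,day_3,174,spotted
175,day_3,175,unspotted
176,day_3,176,unspotted
177,day_3,177,spotted
178,day_3,178,unspotted
179,day_3,179,unspotted
180,day_3,180,spotted
181,day_3,181,unspotted
182,day_3,182,spotted
183,day_3,183,unspotted
184,day_3,184,unspotted
185,day_3,185,spotted
186,day_3,186,unspotted
187,day_3,187,spotted
188,day_3,188,unspotted
189,day_3,189,unspotted
190,day_3,190,spotted
191,day_3,191,unspotted
192,day_3,192,spotted
193,day_3,193,unspotted
194,day_3,194,unspotted
195,day_3,195,spotted
196,day_3,196,unspotted
197,day_3,197,spotted
198,day_3,198,unspotted
199,day_3,199,unspotted
200,day_3,200,spotted
201,day_3,201,unspotted
202,day_3,202,unspotted
203,day_3,203,spotted
204,day_3,204,unspotted
205,day_3,205,spotted
206,day_3,206,unspotted
207,day_3,207,unspotted
208,day_3,208,spotted
209,day_3,209,unspotted
210,day_3,210,spotted
211,day_3,211,unspotted
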