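compound,measured_ic50_nm,measured,hm,rf,gep,gbdt,poly_svm,mix_svm,is_test
1,177.0,2.25,2.39,2.31,2.05,2.06,2.31,2.26,True
2,180.0,2.26,2.39,2.33,2.13,2.06,2.28,2.34,True
3,378.0,2.58,2.43,2.39,2.16,2.06,2.18,2.32,False
4,217.0,2.34,2.4,2.38,2.11,1.94,2.36,2.35,False
5,242.0,2.38,2.37,2.39,2.08,1.92,2.42,2.37,True
6,572.0,2.76,2.44,2.38,2.15,2.16,2.45,2.75,False
7,31.0,1.49,1.32,1.43,1.14,1.34,1.26,1.33,True
8,22.0,1.34,1.17,1.42,1.4,1.41,1.27,1.35,False
9,29.0,1.46,1.34,1.34,1.2,1.45,1.38,1.45,False
10,27.0,1.43,1.42,1.5,1.27,1.45,1.42,1.44,False
11,11.0,1.04,1.38,1.23,1.5,1.21,1.46,1.05,False
12,37.0,1.57,1.34,1.34,1.26,1.51,1.23,1.56,False
13,18.0,1.26,1.87,1.47,1.13,1.35,1.38,1.27,False
14,448.0,2.65,2.27,2.5,2.24,2.07,2.31,2.64,False
15,249.0,2.4,2.26,2.5,2.36,1.99,2.34,2.29,True
16,206.0,2.31,2.43,2.38,2.09,1.98,2.18,2.32,False
17,256.0,2.41,2.36,2.47,2.05,1.99,2.81,2.42,False
18,158.0,2.2,2.35,2.39,2.2,1.89,2.57,2.21,False
19,341.0,2.53,2.26,2.5,2.27,2.01,2.75,2.57,True
20,261.0,2.42,2.95,2.41,2.18,2.0,2.27,2.41,True
21,42.0,1.62,1.38,1.47,1.43,1.55,1.36,1.23,False
22,19.0,1.28,1.23,1.18,1.37,1.36,1.44,1.29,False
23,23.0,1.36,1.38,1.27,1.2,1.4,1.39,1.4,False
24,21.0,1.32,1.2,1.29,1.21,1.39,1.53,1.31,False
25,13.0,1.11,1.17,1.18,1.1,1.26,1.47,1.12,False
26,60.0,1.78,1.25,1.73,1.21,1.67,1.6,1.44,True
27,26.0,1.41,1.74,1.45,1.02,1.41,1.33,1.42,False
28,375.0,2.57,2.3,2.2,2.36,2.46,2.22,2.22,True
29,1571.0,3.2,2.84,2.54,2.26,2.42,3.05,3.19,False
30,170.0,2.23,2.29,2.23,2.47,1.89,2.42,2.22,False
31,1963.0,3.29,2.83,2.42,2.44,2.47,2.93,3.28,False
32,7.6,0.88,1.22,0.73,1.08,1.1,0.62,0.87,False
33,56.0,1.75,1.74,1.81,1.3,1.63,1.36,1.76,False
34,175.0,2.24,1.77,1.84,1.42,1.81,1.44,1.89,False
35,11.0,1.04,1.32,0.91,1.17,1.24,0.93,0.62,False
36,24.0,1.38,1.28,1.4,1.21,1.41,1.11,1.37,False
37,38.0,1.58,1.35,1.15,1.08,1.5,1.23,1.57,False
38,71.0,1.85,2.28,1.9,1.3,1.67,2.32,1.86,False
39,204.0,2.31,2.29,2.03,1.42,1.93,2.45,2.3,False
40,4.6,0.66,1.27,0.92,1.17,1.1,1.0,0.67,False
41,100.0,2.0,1.8,2.08,1.21,1.76,2.33,2.01,False
42,1.9,0.28,0.42,0.57,1.08,0.82,0.51,0.29,False
43,2.8,0.45,0.51,0.87,2.44,0.87,0.91,0.71,False
44,92.0,1.96,2.28,1.87,2.11,1.76,1.63,1.97,False
45,14.0,1.15,0.64,1.08,1.22,1.07,1.5,1.15,True
46,100.0,2.0,1.71,1.74,0.83,1.76,2.33,1.99,False
47,30.0,1.48,1.57,1.78,2.4,1.49,1.76,1.53,False
48,17.0,1.23,1.83,1.65,0.66,1.36,1.56,1.48,False
49,86.0,1.93,1.83,1.77,0.89,1.72,1.76,1.92,False
50,289.0,2.46,1.86,2.18,2.17,2.01,2.12,2.45,False
51,90.0,1.95,1.86,1.78,2.33,1.71,1.6,1.52,False
52,63.0,1.8,1.83,1.88,1.96,1.68,1.91,1.81,False
53,127.0,2.1,1.83,1.94,2.1,1.81,1.95,2.09,False
54,28.0,1.45,2.34,1.65,2.1,1.43,1.84,1.46,False
55,2.1,0.32,1.0,0.99,2.27,1.08,0.66,0.33,False
56,19.0,1.28,1.02,1.07,2.07,1.16,0.97,1.27,False
57,11.0,1.04,1.34,1.04,1.89,1.29,0.87,1.05,False
58,20.0,1.3,1.44,1.08,2.31,1.29,0.97,1.29,False
59,26.0,1.41,1.7,1.39,1.92,1.32,0.99,1.4,False
60,3.2,0.51,0.93,0.79,1.06,1.03,0.73,0.52,False
61,2.5,0.4,0.46,0.48,1.1,0.88,0.49,0.39,False
62,0.9,-0.05,0.52,0.47,1.08,0.74,0.34,0.18,False
63,3.4,0.53,0.55,0.42,1.0,0.95,0.27,0.52,False
64,4.3,0.63,0.61,0.54,0.98,0.99,0.45,0.64,False
65,15.0,1.18,1.04,0.9,0.83,1.0,1.17,0.84,True
66,20.0,1.3,1.05,1.11,1.02,1.39,0.97,1.29,False
67,4.1,0.61,0.62,0.55,0.94,1.08,0.56,0.41,True
68,6.3,0.8,1.09,0.67,0.49,1.06,1.03,0.81,False
69,1.8,0.26,0.44,0.4,0.76,1.11,0.12,0.44,True
70,2.2,0.34,0.53,0.41,0.9,0.99,0.36,0.53,True
71,3.7,0.57,0.58,0.57,0.61,0.97,0.53,0.48,False
72,2.1,0.32,0.5,0.41,0.53,0.88,0.01,0.33,False
73,3.6,0.56,0.53,0.41,0.67,0.99,0.2,0.51,False
74,2.5,0.4,0.55,0.59,0.97,1.02,0.74,0.67,True
75,10.0,1.0,1.27,1.2,0.67,1.19,1.47,1.01,False
76,3.7,0.57,0.4,0.4,1.19,1.0,0.19,0.46,True
77,8.5,0.93,0.48,0.7,1.65,1.33,0.93,0.75,True
78,4.1,0.61,0.39,0.57,0.73,1.0,0.65,0.62,False
79,70.1,1.85,1.13,1.36,1.24,1.67,1.62,1.84,False
80,5.1,0.71,1.39,1.23,0.52,1.03,1.39,1.28,False
81,34.0,1.53,1.46,1.6,0.97,1.5,1.47,1.52,False
82,71.0,1.85,1.93,1.68,0.53,0.85,1.52,1.85,True
83,7.9,0.9,1.33,1.16,0.78,1.07,1.36,1.21,False
84,18.0,1.26,1.37,1.19,1.12,1.35,1.37,1.27,False
85,26.0,1.41,1.41,1.54,1.16,1.43,1.41,1.42,False
86,49.0,1.69,1.44,1.48,1.42,1.59,1.42,1.44,False
87,15.0,1.18,1.39,1.53,0.95,1.31,1.38,1.21,False
88,36.0,1.56,1.41,1.54,1.02,1.25,1.52,1.53,True
89,71.0,1.85,1.43,1.72,1.95,1.67,1.65,1.84,False
90,58.0,1.76,1.32,1.56,1.72,1.62,1.39,1.37,False
91,71.0,1.85,1.38,1.73,1.52,1.67,1.73,1.84,False
92,77.0,1.89,1.31,1.58,1.82,1.7,1.38,1.21,False
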