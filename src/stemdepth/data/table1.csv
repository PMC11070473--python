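id,measured_mm,true_mm
1,34.72,37.42
2,26.48,27.06
3,31.35,32.00
4,39.10,40.08
5,35.76,36.07
6,22.79,26.47
7,34.97,36.01
8,30.12,30.91
9,29.12,30.10
10,23.80,23.71
11,21.88,21.92
12,32.24,31.48
13,27.60,27.52
14,25.16,25.90
15,30.26,29.72
16,30.79,30.43
17,28.21,30.76
18,39.76,40.61
19,28.50,29.61
20,21.48,21.67
21,27.86,28.86
22,22.69,23.56
23,22.41,23.47
24,24.71,24.76
25,22.04,21.85
26,24.91,24.51
27,25.66,26.47
28,23.68,23.77
29,22.42,21.24
30,21.62,21.55
31,22.72,21.66
32,25.64,25.55
33,20.93,20.69
34,21.72,22.29
35,24.12,23.89
36,22.89,21.92
37,21.49,23.53
38,26.74,26.34
39,20.27,20.11
40,26.82,26.62
41,27.66,28.15
42,21.69,21.54
43,23.01,22.46
44,20.25,20.49
45,21.39,22.37
46,23.37,23.27
47,21.34,21.58
48,26.50,24.36
49,20.07,17.55
50,20.05,19.38
51,17.17,17.89
52,21.43,21.52
53,24.82,23.35
54,24.58,22.64
55,25.87,25.62
56,22.81,22.60
57,21.07,20.67
58,21.87,21.74
59,18.46,17.49
60,19.91,19.60
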