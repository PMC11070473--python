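id,measured_mm,true_mm
1,34.57,37.42
2,26.05,27.06
3,29.71,32.00
4,41.17,40.08
5,36.92,36.07
6,22.04,26.47
7,32.50,36.01
8,32.05,30.91
9,28.54,30.10
10,24.55,23.71
11,22.80,21.92
12,32.93,31.48
13,30.91,27.52
14,24.47,25.90
15,31.43,29.72
16,29.78,30.43
17,26.39,30.76
18,43.04,40.61
19,25.83,29.61
20,21.19,21.67
21,31.30,28.86
22,23.62,23.56
23,22.22,23.47
24,23.85,24.76
25,20.60,21.85
26,24.64,24.51
27,24.47,26.47
28,22.89,23.77
29,22.95,21.24
30,22.50,21.55
31,23.06,21.66
32,26.56,25.55
33,21.94,20.69
34,22.00,22.29
35,26.43,23.89
36,24.47,21.92
37,20.83,23.53
38,28.16,26.34
39,20.28,20.11
40,28.40,26.62
41,30.28,28.15
42,23.25,21.54
43,23.80,22.46
44,19.13,20.49
45,24.75,22.37
46,21.55,23.27
47,25.00,21.58
48,28.75,24.36
49,21.30,17.55
50,20.21,19.38
51,17.27,17.89
52,20.81,21.52
53,25.75,23.35
54,29.29,22.64
55,26.59,25.62
56,23.10,22.60
57,20.00,20.67
58,23.68,21.74
59,19.47,17.49
60,22.25,19.60
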