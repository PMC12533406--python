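[meta]
version = synthetic-toy-1

[baseline]
21 = 36.0
22 = 37.8
23 = 39.6
24 = 41.4
25 = 43.2
26 = 45.0
27 = 46.8
28 = 48.6
29 = 50.4
30 = 52.2
31 = 54.0
32 = 55.8
33 = 57.6
34 = 59.400000000000006
35 = 61.2
36 = 63.0
37 = 64.8
38 = 66.6
39 = 68.4
40 = 70.2

[xaa]
A = -5.2
C = -7.4
D = -2.0
E = -2.4
F = -6.6
G = -9.0
H = -6.2
I = -8.6
K = -4.6
L = -7.8
M = -7.0
N = -6.8
O = -1.2
P = 0.0
Q = -4.2
R = -4.4
S = -5.6
T = -6.8
V = -8.2
W = -8.4
Y = -6.4

[yaa]
A = -5.8
C = -7.6
D = -6.4
E = -6.2
F = -7.0
G = -9.0
H = -6.0
I = -8.8
K = -3.4
L = -8.0
M = -7.2
N = -5.6
O = 0.0
P = -3.6
Q = -4.8
R = -3.2
S = -5.4
T = -6.4
V = -8.0
W = -8.6
Y = -6.8

[axial]
D:D = -2.0
K:D = 4.4
K:E = 3.6
K:F = 1.6
K:K = -2.0
Q:F = 1.8
R:D = 2.8
R:E = 2.4
R:R = -1.8

[lateral]
K:D = 1.8
K:E = 1.2
R:D = 1.4

[frameshift]
0 = -1.2
1 = -2.0
2 = 0.0

[terminal]
cterm:*:uncapped = -3.5
nterm:*:uncapped = -5.0

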