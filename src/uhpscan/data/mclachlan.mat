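# McLachlan (1972) amino acid substitution similarity matrix.
# Integer similarity scores 0-9; higher = more similar. Diagonal = identity scores.
   A  R  N  D  C  Q  E  G  H  I  L  K  M  F  P  S  T  W  Y  V
A   8  2  3  3  1  3  4  3  3  2  2  3  3  1  4  4  3  1  1  3
R   2  8  3  1  1  5  3  3  5  1  2  5  1  1  3  4  3  3  2  2
N   3  3  8  5  1  4  4  3  4  1  1  4  2  0  1  5  3  0  2  1
D   3  1  5  8  1  4  5  3  4  1  1  3  2  1  3  3  3  0  1  1
C   1  1  1  1  9  0  0  1  3  1  0  0  3  0  0  2  2  2  1  1
Q   3  5  4  4  0  8  5  2  4  0  3  4  3  0  3  4  3  2  1  2
E   4  3  4  5  0  5  8  3  2  1  1  4  1  0  4  4  4  1  2  2
G   3  3  3  3  1  2  3  8  2  1  1  3  1  0  3  3  2  1  0  2
H   3  5  4  4  3  4  2  2  8  2  2  4  3  4  3  3  4  3  4  2
I   2  1  1  1  1  0  1  1  2  8  5  1  5  3  1  2  3  3  3  5
L   2  2  1  1  0  3  1  1  2  5  8  2  6  5  1  2  3  3  3  5
K   3  5  4  3  0  4  4  3  4  1  2  8  1  0  3  3  3  1  1  2
M   3  1  2  2  3  3  1  1  3  5  6  1  8  5  1  2  3  1  2  4
F   1  1  0  1  0  0  0  0  4  3  5  0  5  9  1  2  1  6  6  3
P   4  3  1  3  0  3  4  3  3  1  1  3  1  1  8  3  3  0  0  2
S   4  4  5  3  2  4  4  3  3  2  2  3  2  2  3  8  5  3  3  2
T   3  3  3  3  2  3  4  2  4  3  3  3  3  1  3  5  8  2  1  3
W   1  3  0  0  2  2  1  1  3  3  3  1  1  6  0  3  2  9  6  2
Y   1  2  2  1  1  1  2  0  4  3  3  1  2  6  0  3  1  6  9  3
V   3  2  1  1  1  2  2  2  2  5  5  2  4  3  2  2  3  2  3  8
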