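# BLOSUM90 amino-acid substitution matrix (half-bit scores)
# Standard NCBI BLAST distribution table, restricted to the 20
# canonical residues (ambiguity codes B/Z/X and stop * removed).
   A  R  N  D  C  Q  E  G  H  I  L  K  M  F  P  S  T  W  Y  V
A   5  -2  -2  -3  -1  -1  -1   0  -2  -2  -2  -1  -2  -3  -1   1   0  -4  -3  -1
R  -2   6  -1  -3  -5   1  -1  -3   0  -4  -3   2  -2  -4  -3  -1  -2  -4  -3  -3
N  -2  -1   7   1  -4   0  -1  -1   0  -4  -4   0  -3  -4  -3   0   0  -5  -3  -4
D  -3  -3   1   7  -5  -1   1  -2  -2  -5  -5  -1  -4  -5  -3  -1  -2  -6  -4  -5
C  -1  -5  -4  -5   9  -4  -6  -4  -5  -2  -2  -4  -2  -3  -4  -2  -2  -4  -4  -2
Q  -1   1   0  -1  -4   7   2  -3   1  -4  -3   1   0  -4  -2  -1  -1  -3  -3  -3
E  -1  -1  -1   1  -6   2   6  -3  -1  -4  -4   0  -3  -5  -2  -1  -1  -5  -4  -3
G   0  -3  -1  -2  -4  -3  -3   6  -3  -5  -5  -2  -4  -5  -3  -1  -3  -4  -5  -5
H  -2   0   0  -2  -5   1  -1  -3   8  -4  -4  -1  -3  -2  -3  -2  -2  -3   1  -4
I  -2  -4  -4  -5  -2  -4  -4  -5  -4   5   1  -4   1  -1  -4  -3  -1  -4  -2   3
L  -2  -3  -4  -5  -2  -3  -4  -5  -4   1   5  -3   2   0  -4  -3  -2  -3  -2   0
K  -1   2   0  -1  -4   1   0  -2  -1  -4  -3   6  -2  -4  -2  -1  -1  -5  -3  -3
M  -2  -2  -3  -4  -2   0  -3  -4  -3   1   2  -2   7  -1  -3  -2  -1  -2  -2   0
F  -3  -4  -4  -5  -3  -4  -5  -5  -2  -1   0  -4  -1   7  -4  -3  -3   0   3  -2
P  -1  -3  -3  -3  -4  -2  -2  -3  -3  -4  -4  -2  -3  -4   8  -2  -2  -5  -4  -3
S   1  -1   0  -1  -2  -1  -1  -1  -2  -3  -3  -1  -2  -3  -2   5   1  -4  -3  -2
T   0  -2   0  -2  -2  -1  -1  -3  -2  -1  -2  -1  -1  -3  -2   1   6  -4  -2  -1
W  -4  -4  -5  -6  -4  -3  -5  -4  -3  -4  -3  -5  -2   0  -5  -4  -4  11   2  -3
Y  -3  -3  -3  -4  -4  -3  -4  -5   1  -2  -2  -3  -2   3  -4  -3  -2   2   8  -3
V  -1  -3  -4  -5  -2  -3  -3  -5  -4   3   0  -3   0  -2  -3  -2  -1  -3  -3   5
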