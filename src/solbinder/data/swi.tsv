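# Solubility-Weighted Index (SWI) per-residue weights
# Source: Bhandari, Gardner & Gardner (2020) Bioinformatics 36:4691-4698, rounded to
# four decimal places.
# High value = favours solubility; the weights are therefore INVERTED (1 - x) after
# min-max normalization before use as a loss term.
A	0.8356
C	0.5479
D	0.9079
E	0.9877
F	0.5329
G	0.7997
H	0.8948
I	0.6784
K	0.9267
L	0.6554
M	0.6297
N	0.8597
P	0.8235
Q	0.7894
R	0.7712
S	0.7441
T	0.8097
V	0.7358
W	0.6375
Y	0.6113
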