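# random_coil_shifts v1 -- random-coil 1H/13C cross-peak positions of the 20
# proteinogenic amino acids in denatured (urea) proteins, DSS-referenced,
# compiled from standard random-coil shift tables. The two X-Pro anchor rows
# (before_pro = True) are the isolated Ca-Ha positions of Ser/Thr preceding a
# proline, used as single-residue reference signals for quantification.
# CH3 correlations are intentionally absent: quantification operates on
# CH/CH2 signals only and methyl regions lie outside the sugar window.
residue,label,c13_ppm,h1_ppm,multiplicity,protons_in_signal,before_pro
A,Ca-Ha,52.5,4.32,CH,1,False
R,Ca-Ha,56.0,4.34,CH,1,False
R,Cd-Hd,43.2,3.20,CH2,2,False
N,Ca-Ha,53.1,4.74,CH,1,False
D,Ca-Ha,54.2,4.64,CH,1,False
C,Ca-Ha,58.2,4.55,CH,1,False
Q,Ca-Ha,55.7,4.34,CH,1,False
Q,Cg-Hg,33.8,2.38,CH2,2,False
E,Ca-Ha,56.6,4.35,CH,1,False
E,Cg-Hg,36.1,2.31,CH2,2,False
G,Ca-Ha,45.1,3.96,CH2,2,False
H,Ca-Ha,55.0,4.73,CH,1,False
I,Ca-Ha,61.1,4.17,CH,1,False
I,Cb-Hb,38.8,1.87,CH,1,False
L,Ca-Ha,55.1,4.34,CH,1,False
K,Ca-Ha,56.2,4.32,CH,1,False
K,Ce-He,41.9,3.02,CH2,2,False
M,Ca-Ha,55.4,4.48,CH,1,False
F,Ca-Ha,57.7,4.62,CH,1,False
P,Ca-Ha,63.3,4.42,CH,1,False
P,Cd-Hd,49.8,3.65,CH2,2,False
S,Ca-Ha,58.3,4.47,CH,1,False
S,Cb-Hb,63.8,3.88,CH2,2,False
S,Ca-Ha,56.6,4.71,CH,1,True
T,Ca-Ha,61.8,4.35,CH,1,False
T,Cb-Hb,69.8,4.24,CH,1,False
T,Ca-Ha,60.1,4.60,CH,1,True
W,Ca-Ha,57.5,4.66,CH,1,False
Y,Ca-Ha,57.9,4.55,CH,1,False
V,Ca-Ha,62.2,4.12,CH,1,False
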