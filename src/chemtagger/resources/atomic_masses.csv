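element,monoisotopic_mass,average_mass
H,1.0078250319,1.008
B,11.0093054,10.81
C,12.0000000,12.011
N,14.0030740052,14.007
O,15.9949146221,15.999
F,18.9984032,18.998
Na,22.98976928,22.990
Mg,23.98504170,24.305
Al,26.98153853,26.982
Si,27.97692653,28.085
P,30.97376199,30.974
S,31.97207117,32.06
Cl,34.96885268,35.45
K,38.96370649,39.098
Ca,39.96259086,40.078
Ti,47.94794198,47.867
Cr,51.94050623,51.996
Mn,54.93804391,54.938
Fe,55.93493633,55.845
Co,58.93319429,58.933
Ni,57.93534241,58.693
Cu,62.92959772,63.546
Zn,63.92914201,65.38
Se,79.9165218,78.971
Br,78.9183376,79.904
Pd,105.9034804,106.42
Ag,106.9050916,107.868
Sn,119.90220163,118.710
I,126.9044719,126.904
Pt,194.9647917,195.084
Au,196.96656879,196.967
Hg,201.97064340,200.592
Pb,207.9766525,207.2
Li,7.0160034366,6.94
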