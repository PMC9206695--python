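compound,D0_mean,D2_mean,D4_mean,D6_mean,D8_mean,D10_mean
Phenylethyl Alcohol,3622.04,1044.49,1514.35,2186.36,3636.99,3935.78
2-methyl-1-Propanol,ND,33.79,57.62,273.63,489.67,16280.09
3-methyl-1-Butanol,ND,570.81,816.92,3896.08,4922.36,3830.97
2-phenoxy-Ethanol,1360.17,251.37,66.17,254.19,439.94,924.99
1-Triacontanol,ND,175.23,40.41,10605.38,3509.15,1040.19
1-Hexacosanol,ND,343.02,100.64,6555.62,2045.77,1250.21
1-Dodecanol,ND,96.87,19.54,444.37,873.75,391.8
1-Hexadecanol,ND,19.48,80.71,518.09,925.01,305.18
2-O-decyl-Threitol,3669,46.34,128.94,434.45,731.42,634.47
2-ethyl-2-methyl-Tridecanol,ND,12.68,13.28,1023.48,2513.16,1653.45
2-(2-butoxyethoxy)-Ethanol,ND,93.29,95.33,493.28,772.57,1143.66
6-Methyl-1-octanol,ND,ND,ND,517.2,ND,ND
2-Furanmethanol,3550.9,118.16,70.06,ND,ND,ND
Octaethylene glycol,542.35,57.55,25.39,ND,ND,ND
"9,12-Octadecadien-1-ol",ND,464.43,186.01,ND,ND,ND
2-ethyl-1-Hexanol,ND,54.63,58.92,ND,ND,ND
2-Isopropyl-5-methyl-1-heptanol,ND,27.8,60.7,ND,ND,ND
"3,7-dimethyl-1,6-Octadien-3-ol",ND,46.97,16.98,ND,ND,ND
3-(methylthio)-1-Propanol,ND,47.58,16.58,ND,ND,ND
1-Heptadecanol,ND,33.45,24.83,ND,ND,ND
1-Undecanol,ND,ND,28.77,ND,ND,ND
5-methyl-2-(1-methylethenyl)-4-Hexen-1-ol,ND,19.47,ND,ND,ND,ND
4-methyl-1-Heptanol,ND,13.29,ND,ND,ND,ND
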