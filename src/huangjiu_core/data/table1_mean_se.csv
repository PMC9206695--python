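compound,D0_mean,D0_se,D2_mean,D2_se,D4_mean,D4_se,D6_mean,D6_se,D8_mean,D8_se,D10_mean,D10_se
Phenylethyl Alcohol,3622.04,41.20,1044.49,27.29,1514.35,58.50,2186.36,67.92,3636.99,65.38,3935.78,26.14
2-methyl-1-Propanol,ND,ND,33.79,1.66,57.62,2.02,273.63,10.84,489.67,5.50,"16,280.09",759.33
3-methyl-1-Butanol,ND,ND,570.81,5.09,816.92,11.53,3896.08,135.25,4922.36,22.90,3830.97,93.43
2-phenoxy-Ethanol,1360.17,29.66,251.37,8.64,66.17,1.44,254.19,7.46,439.94,12.84,924.99,14.49
1-Triacontanol,ND,ND,175.23,4.79,40.41,0.60,"10,605.38",703.62,3509.15,128.55,1040.19,70.22
1-Hexacosanol,ND,ND,343.02,19.80,100.64,0.71,6555.62,217.16,2045.77,32.04,1250.21,64.71
1-Dodecanol,ND,ND,96.87,1.95,19.54,0.92,444.37,31.65,873.75,24.19,391.80,4.39
1-Hexadecanol,ND,ND,19.48,0.40,80.71,2.16,518.09,23.46,925.01,8.90,305.18,3.88
2-O-decyl-Threitol,3669.00,34.11,46.34,1.99,128.94,3.39,434.45,15.03,731.42,5.80,634.47,20.50
2-ethyl-2-methyl-Tridecanol,ND,ND,12.68,1.42,13.28,0.12,1023.48,52.55,2513.16,26.41,1653.45,38.04
2-(2-butoxyethoxy)-Ethanol,ND,ND,93.29,1.77,95.33,2.56,493.28,6.34,772.57,20.62,1143.66,45.92
6-Methyl-1-octanol,ND,ND,ND,ND,ND,ND,517.20,16.00,ND,ND,ND,ND
2-Furanmethanol,3550.90,42.75,118.16,2.40,70.06,1.16,ND,ND,ND,ND,ND,ND
Octaethylene glycol,542.35,26.68,57.55,2.43,25.39,2.39,ND,ND,ND,ND,ND,ND
"9,12-Octadecadien-1-ol",ND,ND,464.43,13.11,186.01,7.77,ND,ND,ND,ND,ND,ND
2-ethyl-1-Hexanol,ND,ND,54.63,3.49,58.92,0.18,ND,ND,ND,ND,ND,ND
2-Isopropyl-5-methyl-1-heptanol,ND,ND,27.80,1.29,60.70,0.45,ND,ND,ND,ND,ND,ND
"3,7-dimethyl-1,6-Octadien-3-ol",ND,ND,46.97,1.39,16.98,0.73,ND,ND,ND,ND,ND,ND
3-(methylthio)-1-Propanol,ND,ND,47.58,0.49,16.58,0.32,ND,ND,ND,ND,ND,ND
1-Heptadecanol,ND,ND,33.45,0.68,24.83,0.62,ND,ND,ND,ND,ND,ND
1-Undecanol,ND,ND,ND,ND,28.77,0.65,ND,ND,ND,ND,ND,ND
5-methyl-2-(1-methylethenyl)-4-Hexen-1-ol,ND,ND,19.47,0.19,ND,ND,ND,ND,ND,ND,ND,ND
4-methyl-1-Heptanol,ND,ND,13.29,0.22,ND,ND,ND,ND,ND,ND,ND,ND
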