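compound,is_straight_chain_saturated_alkan1ol,carbon_count
Phenylethyl Alcohol,false,8
2-methyl-1-Propanol,false,4
3-methyl-1-Butanol,false,5
2-phenoxy-Ethanol,false,8
1-Triacontanol,true,30
1-Hexacosanol,true,26
1-Dodecanol,true,12
1-Hexadecanol,true,16
2-O-decyl-Threitol,false,14
2-ethyl-2-methyl-Tridecanol,false,16
2-(2-butoxyethoxy)-Ethanol,false,8
6-Methyl-1-octanol,false,9
2-Furanmethanol,false,5
Octaethylene glycol,false,16
"9,12-Octadecadien-1-ol",false,18
2-ethyl-1-Hexanol,false,8
2-Isopropyl-5-methyl-1-heptanol,false,11
"3,7-dimethyl-1,6-Octadien-3-ol",false,10
3-(methylthio)-1-Propanol,false,4
1-Heptadecanol,true,17
1-Undecanol,true,11
5-methyl-2-(1-methylethenyl)-4-Hexen-1-ol,false,10
4-methyl-1-Heptanol,false,8
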