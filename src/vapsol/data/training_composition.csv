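type,formula_family,sizes,count
hydrocarbons,CnH2n+2,1-10,10
acids,CnH2n+1COOH,0-8,9
alcohols,CnH2n+1OH,1-9,9
ketones,CnH2nO/C6H5COCH3,3-7,6
amines,CnH2n+1NH2,1-6,5
aldehydes,Cn-1H2n-1CHO/C6H5CHO,3-6,5
nitriles,CnH2n+1CN,1;3-6,5
organic chlorides,CnH2n+1Cl,1;3-6,5
benzene derivatives,C6H6/C6H5OCH3/C6H5OCH2CH3/C6H5CH2OCH3/C6H5CnH2n+1,1;2;4,7
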