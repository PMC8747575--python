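polymer,polymer_formula,re_name,re_formula,re_smiles
poly(acrylic acid),(C3H4O2)n,propanoic acid,CH3CH2COOH,CCC(=O)O
poly(allyl cyanide),(C4H5N)n,butanenitrile,CH3CH2CH2CN,CCCC#N
polyacrylonitrile,(C3H3N)n,propanenitrile,CH3CH2CN,CCC#N
polybutylene,(C4H8)n,butane,CH3CH2CH2CH3,CCCC
polyethylene (HDPE),(C2H4)n,ethane,CH3CH3,CC
poly(ethylene glycol),(C2H4O)n,dimethyl ether,CH3OCH3,COC
cis-1-4-polyisoprene,(C5H8)n,2-methyl-2-butene,CH3CHC(CH3)2,CC=C(C)C
polyisobutene,(C4H8)n,isobutane,(CH3)2CHCH3,CC(C)C
polymethacrylonitrile,(C4H5N)n,isobutyronitrile,(CH3)2CHCN,CC(C)C#N
poly(methyl methacrylate),(C5H8O2)n,methyl butyrate,CH3CH2CH2COOCH3,CCCC(=O)OC
polypropylene,(C3H6)n,propane,CH3CH2CH3,CCC
polystyrene,(C8H8)n,ethylbenzene,C6H5C2H5,CCc1ccccc1
poly(vinyl alcohol),(C2H4O)n,ethanol,CH3CH2OH,CCO
poly(vinyl acetate),(C4H6O2)n,ethyl acetate,CH3COOCH2CH3,CC(=O)OCC
poly(vinyl chloride),(C2H3Cl)n,chloroethane,CH3CH2Cl,CCCl
poly(vinyl ethyl ether),(C4H6O)n,diethyl ether,CH3CH2OCH2CH3,CCOCC
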