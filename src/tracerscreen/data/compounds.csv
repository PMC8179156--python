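name,formula,synonyms,printed_mz,printed_adduct
SFN-GSH,C16H28N4O7S3,sulforaphane-glutathione conjugate,485.1184,[M+H]+
SFN-gammaEC,C14H25N3O6S3,sulforaphane-gamma-glutamylcysteine conjugate,428.0979,[M+H]+
SFN-Cys,C9H18N2O3S3,sulforaphane-cysteine conjugate,299.0555,[M+H]+
4MSB-NH2,C5H13NOS,4-methylsulfinyl-n-butyl amine,136.0797,[M+H]+
raphanusamic acid,C4H5NO2S2,"RA;2-thioxo-1,3-thiazolidine-4-carboxylic acid",161.9683,[M-H]-
glutathione,C10H17N3O6S,GSH,306.0759,[M-H]-
sulforaphane,C6H11NOS2,SFN;4-methylsulfinyl-n-butyl isothiocyanate,,
procysteine,C4H5NO3S,"pCys;1,3-thiazolidin-2-one-4-carboxylic acid",,
cysteine,C3H7NO2S,Cys,,
gamma-glutamylcysteine,C8H14N2O5S,gammaEC,,
glucoiberin,C11H21NO10S3,3MSP,,
glucoraphanin,C12H23NO10S3,4MSB,,
glucoalyssin,C13H25NO10S3,5MSP,,
glucohesperalin,C14H27NO10S3,6MSH,,
glucoibarin,C15H29NO10S3,7MSH,,
glucohirsutin,C16H31NO10S3,8MSO,,
glucoiberverin,C11H21NO9S3,3MTP,,
glucoerucin,C12H23NO9S3,4MTB,,
glucoberteroin,C13H25NO9S3,5MTP,,
glucolesquerellin,C14H27NO9S3,6MTH,,
7-methylthioheptyl glucosinolate,C15H29NO9S3,7MTH,,
8-methylthiooctyl glucosinolate,C16H31NO9S3,8MTO,,
3-hydroxypropyl glucosinolate,C10H19NO10S2,3OHP,,
4-hydroxybutyl glucosinolate,C11H21NO10S2,4OHB,,
glucomalcomin,C17H23NO11S2,3OBzP,,
4-benzoyloxybutyl glucosinolate,C18H25NO11S2,4OBzB,,
gluconasturtiin,C15H21NO9S2,PhE,,
glucobrassicin,C16H20N2O9S2,I3G,,
neoglucobrassicin,C17H22N2O10S2,1MI3G,,
4-methoxyglucobrassicin,C17H22N2O10S2,4MI3G,,
4-hydroxyglucobrassicin,C16H20N2O10S2,4OHI3G,,
sinigrin,C10H17NO9S2,allyl glucosinolate,,
glucoraphenin,C12H21NO10S3,4MSB(en),,
glucotropaeolin,C14H19NO9S2,Bn;benzyl glucosinolate,,
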