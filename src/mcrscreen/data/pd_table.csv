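chemical,pd_mg_per_kg_day,source_code,basis
"1,1,1-Trichloroethane",2,1,RfD
"1,1,1,2-Tetrachloroethane",0.03,1,RfD
"1,1,2-Trichloro-1,2,2-trifluoroethane",30,1,RfD
"1,1,2-Trichloroethane",0.004,1,RfD
"1,1-Dichloroethane",0.07,8,RfD
"1,1-Dichloroethene",0.05,1,RfD
"1,2,3-Trichloropropane",0.004,1,RfD
"1,2,4-Trichloro-Benzene",0.01,1,RfD
"1,2,4-Trimethylbenzene",0.05,10,RfD
"1,2-Dibromo-3-chloropropane",0.0002,10,RfD
"1,2-Dibromoethane",0.009,1,RfD
"1,2-Dichlorobenzene",0.09,1,RfD
"1,2-Dichloropropane",0.09,14,MRL
"1,4-Dichlorobenzene",0.07,14,MRL
"2,4-D",0.005,2,RfD
"2,6-Diethylaniline",0.006,2,RfD
2-Chloro-4-isopropylamino-6-amino-s-triazine,0.0018,2,RfD
Acetochlor,0.02,1,RfD
Acetone,0.9,1,RfD
Acrylonitrile,0.002,1,RfD
Alachlor,0.01,2,RfD
Aldicarb,0.00027,3,RfD
Aldicarb sulfone,0.00027,3,RfD
Aldicarb sulfoxide,0.00027,15,RfD
alpha-HCH,0.008,16,RfD
Aluminum,1,10,RfD
Antimony,0.0004,1,RfD
Arsenic,0.0003,1,RfD
Atrazine,0.0019,2,RfD
Barium,0.2,1,RfD
Bentazon,0.03,2,RfD
Benzene,0.004,1,RfD
Beryllium,0.002,1,RfD
Boron,0.2,1,RfD
Bromacil,0.1,2,RfD
Bromobenzene,0.008,1,RfD
Bromochloro Methane,0.04,10,RfD
Bromodichloro Methane,0.02,1,RfD
Bromoxynil,0.015,2,RfD
Butylate,0.05,2,RfD
Cadmium,0.0005,1,RfD
Carbaryl,0.1,2,RfD
Carbofuran,0.00006,2,RfD
Carbon disulfide,0.1,1,RfD
Chloramben methyl ester,0.014,4,RfD
Chlorobenzene,0.02,1,RfD
Chloromethane,0.01,1,RfD
Chlorpyrifos,0.00003,2,RfD
Chromium,0.003,1,RfD
"cis-1,2-Dichloroethene",0.002,1,RfD
Clopyralid,0.15,19,RfD
Cobalt,0.06,10,RfD
Copper,0.01,12,RfD
Cyanazine,0.00026,5,RfD
DCPA,0.01,2,RfD
Diazinon,0.0002,2,RfD
Dibromochloro-methane,0.02,1,RfD
Dichlorodifluoromethane,0.2,1,RfD
Dichloromethane,0.06,1,RfD
Dieldrin,0.00005,2,RfD
Diethyl ether,0.2,1,RfD
Diisopropyl ether,0.1,10,RfD
Dinoseb,0.001,1,RfD
Diuron,0.003,2,RfD
EPTC,0.0025,2,RfD
Ethoprop,0.0001,2,RfD
Ethyl methyl ketone,0.6,1,RfD
Ethylbenzene,0.1,1,RfD
Fluometuron,0.005,2,RfD
Fluoride,60,1,RfD
Hexachloro-butadiene,6.70E-05,9,RfD
Isopropylbenzene,0.1,1,RfD
Lead,0.0005,7,MCL
Lindane,0.0003,1,RfD
Linuron,0.0077,2,RfD
Lithium,0.02,10,RfD
Manganese,0.14,1,RfD
Methyl parathion,0.00002,2,RfD
Methyl tert-butyl ether,0.01,10,RfD
Methyl tert-pentyl ether,0.04,10,RfD
Metolachlor,0.1,2,RfD
Metribuzin,0.013,2,RfD
Molinate,0.001,17,RfD
Molybdenum,0.005,1,RfD
m- + p-Xylene,0.2,1,RfD
Naphthalene,0.02,1,RfD
Nickel,0.02,1,RfD
Nitrate,1.6,1,RfD
Nitrite,0.1,1,RfD
Norflurazon,0.015,2,RfD
o-Xylene,0.2,1,RfD
"p,p'-DDE",0.0005,18,RfD
Picloram,0.2,2,RfD
Prometon,0.05,2,RfD
Propoxur,0.005,2,RfD
Selenium,0.005,1,RfD
Silver,0.005,1,RfD
Simazine,0.0018,2,RfD
Strontium,0.6,1,RfD
Styrene,0.2,1,RfD
Tebuthiuron,0.07,2,RfD
Terbacil,0.013,2,RfD
Tetrachloro ethene,0.01,1,RfD
Tetrachloro methane,0.004,1,RfD
Thallium,0.00008,10,RfD
Toluene,0.08,1,RfD
"trans-1,2-Dichloroethene",0.02,1,RfD
Tribromomethane,0.02,1,RfD
Trichloroethene,0.05,13,TDI
Trichlorofluoro-methane,0.3,1,RfD
Trichloromethane,0.01,1,RfD
Uranium (natural),30,7,MCL
Vanadium,0.01,11,MRL
Vinyl chloride,0.003,1,RfD
Zinc,0.3,1,RfD
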