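id,name,smiles,class
nerol,Nerol,CC(C)=CCC/C(C)=C\CO,monoterpenoid
geraniol,Geraniol,CC(C)=CCC/C(C)=C/CO,monoterpenoid
p_cymene,p-Cymene,Cc1ccc(C(C)C)cc1,monoterpenoid
limonene,(R)-(+)-Limonene,CC1=CC[C@@H](CC1)C(=C)C,monoterpenoid
borneol,(+)-Borneol,CC1(C)[C@@H]2CC[C@@]1(C)[C@H](O)C2,monoterpenoid
eucalyptol,Eucalyptol,CC12CCC(CC1)C(C)(C)O2,monoterpenoid
linalool,Linalool,CC(C)=CCCC(C)(O)C=C,monoterpenoid
alpha_terpineol,alpha-Terpineol,CC1=CCC(CC1)C(C)(C)O,monoterpenoid
beta_citronellol,beta-Citronellol,OCC[C@@H](C)CCC=C(C)C,monoterpenoid
menthol,(-)-Menthol,C[C@@H]1CC[C@H](C(C)C)[C@@H](O)C1,monoterpenoid
carvone,(R)-Carvone,CC1=CC(=O)C[C@@H](C1)C(=C)C,monoterpenoid
citral,Citral,CC(C)=CCC/C(C)=C/C=O,monoterpenoid
citronellal,(S)-Citronellal,O=CC[C@H](C)CCC=C(C)C,monoterpenoid
geranic_acid,Geranic acid,CC(C)=CCC/C(C)=C/C(=O)O,monoterpenoid
linalool_oxide,Linalool oxide,CC1(C=C)CCC(C(C)(C)O)O1,monoterpenoid
alpha_terpinyl_acetate,(+/-)-alpha-Terpinyl acetate,CC1=CCC(CC1)C(C)(C)OC(C)=O,monoterpenoid
beta_caryophyllene,beta-Caryophyllene,CC1=CCCC(=C)C2CC(C)(C)C2CC1,sesquiterpenoid
alpha_cedrene,(-)-alpha-Cedrene,CC1CCC2C(C)(C)C3CC12CC=C3C,sesquiterpenoid
alpha_neoclovene,(-)-alpha-Neoclovene,CC1=CCC23CC(C)(C)C2CCCC13C,sesquiterpenoid
valencene,(+)-Valencene,CC1CCC=C2CCC(C(C)=C)CC12C,sesquiterpenoid
z_nerolidol,(Z)-Nerolidol,CC(C)=CCC/C(C)=C\CCC(C)(O)C=C,sesquiterpenoid
alpha_bisabolol,(-)-alpha-Bisabolol,CC1=CC[C@@H](CC1)[C@](C)(O)CCC=C(C)C,sesquiterpenoid
guaiazulene,Guaiazulene,Cc1ccc(C(C)C)c2ccc(C)c2c1,sesquiterpenoid
farnesol,(E-E)-Farnesol,CC(C)=CCC/C(C)=C/CC/C(C)=C/CO,sesquiterpenoid
beta_ionone,beta-Ionone,CC(=O)/C=C/C1=C(C)CCCC1(C)C,norisoprenoid
geranyl_acetone,Geranyl acetone,CC(=O)CC/C=C(C)/CCC=C(C)C,norisoprenoid
theaspirane,(+/-)-Theaspirane,CC1CCC2(O1)C(C)=CCCC2(C)C,norisoprenoid
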