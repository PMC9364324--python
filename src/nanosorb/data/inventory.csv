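# Reconstructed inventory of enteric microbial metabolites: names/categories
# follow the published overview where listed; remaining members and the
# per-review provenance are a deterministic reconstruction encoding the
# published cumulative discovery totals (137/161/170). Multi-category
# records use '|' between category labels.
name,category,smiles,source_reviews
N-formylated peptides,MAMPs,,1
lipoteichoic acid,MAMPs,,1
peptidoglycan,MAMPs,,1
lipopeptides,MAMPs,,1
lipopolysaccharides,MAMPs,,1
glucans,MAMPs,,1
mannans,MAMPs,,1
chitins,MAMPs,,1
capsular polysaccharides,MAMPs,,1
muramyl dipeptide,MAMPs,,1
menaquinone-4,vitamins,CC1=C(C(=O)c2ccccc2C1=O)C/C=C(C)/CC/C=C(C)/CC/C=C(C)/CCC=C(C)C,1
cobalamin,vitamins,,1
biotin,vitamins,OC(=O)CCCCC1SCC2NC(=O)NC12,1
folate,vitamins,Nc1nc2ncc(CNc3ccc(cc3)C(=O)NC(CCC(=O)O)C(=O)O)nc2c(=O)[nH]1,1
thiamine,vitamins,Cc1ncc(C[n+]2csc(CCO)c2C)c(N)n1,1
riboflavin,vitamins,,1
pyridoxine,vitamins,Cc1ncc(CO)c(CO)c1O,1
niacin,vitamins,OC(=O)c1cccnc1,1
pantothenic acid,vitamins,CC(C)(CO)C(O)C(=O)NCCC(=O)O,1
"5,10-methenyltetrahydropteroylglutamate",vitamins,,1
polyglutamylated folate,vitamins,,1
acetic acid,SCFAs,CC(=O)O,1
propionic acid,SCFAs,CCC(=O)O,1
butyric acid,SCFAs,CCCC(=O)O,1
isobutyric acid,SCFAs,CC(C)C(=O)O,1
hexanoic acid,SCFAs,CCCCCC(=O)O,1
valeric acid,SCFAs,CCCCC(=O)O,1
isovaleric acid,SCFAs,CC(C)CC(=O)O,1
2-methylbutyric acid,SCFAs,CCC(C)C(=O)O,1
cholic acid,PBAs,,1
chenodeoxycholic acid,PBAs,,1
12-dehydrocholate,SBAs,,1
7-ketodeoxycholic acid,SBAs,,1
7-dehydrochenodeoxycholate,SBAs,,1
3-dehydrocholic acid,SBAs,,1
3-dehydrochenodeoxycholic acid,SBAs,,1
isocholic acid,SBAs,,1
isochenodeoxycholic acid,SBAs,,1
lithocholic acid,SBAs,,1
deoxycholic acid,SBAs,,1
allolithocholic acid,SBAs,,1
allodeoxycholic acid,SBAs,,1
ursocholic acid,SBAs,,1
ursodeoxycholic acid,SBAs,,1
hyocholic acid,SBAs,,1
hyodeoxycholic acid,SBAs,,1
7-oxolithocholic acid,SBAs,,1
taurocholic acid,CBAs,,1
glycocholic acid,CBAs,,1
taurohyocholic acid,CBAs,,1
taurochenodeoxycholic acid,CBAs,,1
glycochenodeoxycholic acid,CBAs,,1
glycodeoxycholic acid,CBAs,,1
taurodeoxycholic acid,CBAs,,1
N-acetyltryptophan,tryptophan,CC(=O)NC(Cc1c[nH]c2ccccc12)C(=O)O,1
indoleacetic acid,tryptophan,OC(=O)Cc1c[nH]c2ccccc12,1
indoleacetylglycine,tryptophan,OC(=O)CNC(=O)Cc1c[nH]c2ccccc12,1
indole,tryptophan,c1ccc2[nH]ccc2c1,1
indoxyl sulfate,tryptophan,OS(=O)(=O)Oc1c[nH]c2ccccc12,1
indole-3-propionic acid,tryptophan,OC(=O)CCc1c[nH]c2ccccc12,1
melatonin,tryptophan,CC(=O)NCCc1c[nH]c2ccc(OC)cc12,2
melatonin 6-sulfate,tryptophan,,2
5-hydroxyindole,tryptophan,Oc1ccc2[nH]ccc2c1,2
indoleacrylic acid,tryptophan,OC(=O)/C=C/c1c[nH]c2ccccc12,2
indoleethanol,tryptophan,OCCc1c[nH]c2ccccc12,2
tryptamine,tryptophan,NCCc1c[nH]c2ccccc12,2
3-methylindole,tryptophan,Cc1c[nH]c2ccccc12,2
indole-3-carboxylate,tryptophan,OC(=O)c1c[nH]c2ccccc12,2
putrescine,polyamines,NCCCCN,2
cadaverine,polyamines,NCCCCCN,2
spermidine,polyamines,NCCCCNCCCN,2
spermine,polyamines,NCCCNCCCCNCCCN,2
methylamine,choline,CN,2
dimethylamine,choline,CNC,2
trimethylamine,choline,CN(C)C,2
trimethylamine-N-oxide,choline,C[N+](C)(C)[O-],2
dimethylglycine,choline,CN(C)CC(=O)O,2
betaine,choline,C[N+](C)(C)CC(=O)[O-],2
noradrenaline,neurotransmitters,NCC(O)c1ccc(O)c(O)c1,2
gamma-aminobutyric acid,neurotransmitters,NCCCC(=O)O,2
dopamine,neurotransmitters,NCCc1ccc(O)c(O)c1,2
histamine,neurotransmitters,NCCc1c[nH]cn1,2
benzoate,phenolic,OC(=O)c1ccccc1,2
hippurate,phenolic,OC(=O)CNC(=O)c1ccccc1,2
phenylacetate,phenolic,OC(=O)Cc1ccccc1,2
phenylpropionate,phenolic,OC(=O)CCc1ccccc1,2
3-hydroxycinnamate,phenolic,OC(=O)/C=C/c1cccc(O)c1,2
2-hydroxyhippurate,phenolic,OC(=O)CNC(=O)c1ccccc1O,2
3-hydroxyhippurate,phenolic,OC(=O)CNC(=O)c1cccc(O)c1,2
2-hydroxybenzoate,phenolic,OC(=O)c1ccccc1O,2
3-hydroxybenzoate,phenolic,OC(=O)c1cccc(O)c1,2
4-hydroxybenzoate,phenolic,OC(=O)c1ccc(O)cc1,2
4-hydroxyphenylacetate,phenolic,OC(=O)Cc1ccc(O)cc1,2
3-hydroxyphenylpropionate,phenolic,OC(=O)CCc1cccc(O)c1,2
4-hydroxyphenylpropionate,phenolic,OC(=O)CCc1ccc(O)cc1,2
"3,4-dihydroxyphenylpropionate",phenolic,OC(=O)CCc1ccc(O)c(O)c1,2
4-cresol,phenolic,Cc1ccc(O)cc1,2
4-cresyl sulfate,phenolic,Cc1ccc(OS(=O)(=O)O)cc1,2
4-cresyl glucuronide,phenolic,,2
phenylacetylglutamine,phenolic,NC(=O)CCC(NC(=O)Cc1ccccc1)C(=O)O,2
phenylacetylglycine,phenolic,OC(=O)CNC(=O)Cc1ccccc1,3
phenylpropionylglycine,phenolic,OC(=O)CNC(=O)CCc1ccccc1,3
cinnamoylglycine,phenolic,OC(=O)CNC(=O)/C=C/c1ccccc1,3
4-ethylphenyl sulfate,phenolic,CCc1ccc(OS(=O)(=O)O)cc1,3
phenol,phenolic,Oc1ccccc1,3
s-equol,phenolic,,3
sphingomyelin,lipid,,3
cholesterol,lipid,,3
phosphatidylcholine,lipid,,3
phosphoethanolamines,lipid,,3
triglycerides,lipid,,3
sphingolipids,lipid,,3
linoleic acid,lipid,CCCCC/C=C\C/C=C\CCCCCCCC(=O)O,3
caproic acid derivatives,lipid,,3
endocannabinoids,lipid,,3
microbial anti-inflammatory molecule,proteins/enzymes,,3
bacteriocins,proteins/enzymes,,3
alpha-hemolysin,proteins/enzymes,,3
Amuc_1100,proteins/enzymes,,3
serine protease,proteins/enzymes,,3
serpins,proteins/enzymes,,3
lactocepin,proteins/enzymes,,3
methanol,other,CO,3
ethanol,other,CCO,3
formate,other,OC=O,3
succinate,other,OC(=O)CCC(=O)O,3
lysine,other,NCCCCC(N)C(=O)O,3
glucose,other,OCC1OC(O)C(O)C(O)C1O,3
urea,other,NC(N)=O,3
alpha-ketoisovalerate,other,CC(C)C(=O)C(=O)O,3
creatine,other,CN(CC(=O)O)C(=N)N,3
creatinine,other,CN1CC(=O)N=C1N,3
imidazole propionate,other,OC(=O)CCc1cnc[nH]1,3
hydrogen peroxide,other,OO,3
reactive aldehydes,other,,3
quorum sensing molecules,other,,3
D-lactate,other,CC(O)C(=O)O,3
mycolactone,other,,4
acetylcholine,tryptophan|neurotransmitters,CC(=O)OCC[N+](C)(C)C,4
5-hydroxytryptamine,tryptophan|neurotransmitters,NCCc1c[nH]c2ccc(O)cc12,4
lipoarabinomannan,MAMPs,,4
zymosan,MAMPs,,4
"beta-1,3-glucan",MAMPs,,4
teichoic acid,MAMPs,,4
lipomannan,MAMPs,,4
CpG dinucleotides,MAMPs,,4
exopolysaccharides,MAMPs,,4
porins,MAMPs,,4
pili adhesins,MAMPs,,4
trehalose dimycolate,MAMPs,,4
arabinogalactan,MAMPs,,4
mycolic acids,MAMPs,,4
phosphorylcholine conjugates,MAMPs,,5
kynurenine,tryptophan,NC(CC(=O)c1ccccc1N)C(=O)O,5
conjugated linoleic acid,lipid,,5
lysophosphatidylcholine,lipid,,5
ceramides,lipid,,5
palmitic acid,lipid,CCCCCCCCCCCCCCCC(=O)O,5
flagellin,proteins/enzymes,,5
invasin,proteins/enzymes,,5
bile salt hydrolase,proteins/enzymes,,5
beta-glucuronidase,proteins/enzymes,,6
azoreductase,proteins/enzymes,,6
ammonia,other,N,7
hydrogen sulfide,other,S,7
ethanolamine,other,NCCO,8
"2,3-butanediol",other,CC(O)C(O)C,8
acetoin,other,CC(=O)C(C)O,9
polyphosphate,other,,9
4-aminobenzoate,other,Nc1ccc(cc1)C(=O)O,10
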