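target,auc_fred,auc_rocs,auc_alignit,ef1_fred,ef1_rocs,ef1_alignit
aa2ar,0.64,0.72,0.57,3.1,24.4,1.5
abl1,0.74,0.58,0.69,15.9,17,11
ace,0.77,0.74,0.71,17.6,12.5,8.6
aces,0.74,0.47,0.52,13.7,3.4,5.7
ada,0.73,0.92,0.88,17,52,34
ada17,0.78,0.72,0.65,22.2,11.8,13.4
adrb1,0.76,0.53,0.63,6.5,12.2,12.6
adrb2,0.78,0.51,0.52,7.8,10,9.6
akt1,0.60,0.34,0.65,2,4.1,5.8
akt2,0.64,0.41,0.64,5.1,10.2,15.3
aldr,0.68,0.66,0.61,18.1,34.4,24.4
ampc,0.72,0.74,0.73,32.5,31.1,27
andr,0.68,0.71,0.61,17.3,15.6,14.1
aofb,0.72,0.40,0.48,1.6,3.3,3.3
bace1,0.55,0.32,0.64,15.5,1.7,4.1
braf,0.73,0.56,0.61,20.3,28.2,24.9
cah2,0.63,0.59,0.75,4.6,5.2,4.7
casp3,0.53,0.48,0.53,3.5,1.5,2
cdk2,0.75,0.70,0.63,11.8,14.7,9.9
comt,1.00,0.88,0.93,94.2,36.2,36.3
cp2c9,0.65,0.46,0.47,8.3,1.7,3.3
cp3a4,0.65,0.52,0.47,4.7,3.9,3
csf1r,0.72,0.68,0.65,26,27.6,25.2
cxcr4,0.89,0.91,0.70,30.6,41.9,33.6
def,0.90,0.84,0.93,32.5,40.9,47.2
dhi1,0.78,0.68,0.56,10.9,14.4,1.8
dpp4,0.76,0.71,0.65,11.1,14.5,6
drd3,0.83,0.55,0.52,13.6,5,2.7
dyr,0.61,0.74,0.73,12.7,35.5,23.4
egfr,0.67,0.78,0.78,3.1,19.8,23.3
esr1,0.89,0.77,0.85,43.7,46.2,37.9
esr2,0.92,0.82,0.86,41.3,39,30.6
fa10,0.76,0.71,0.55,17.8,16,8.2
fa7,0.79,0.71,0.58,41.7,21.7,13.9
fabp4,0.87,0.78,0.65,25.1,33.9,34
fak1,0.91,0.94,0.73,47.5,49.5,22.7
fgfr1,0.67,0.52,0.64,5.5,1.4,2.9
fkb1a,0.66,0.59,0.68,6.3,6.4,8.2
fnta,0.70,0.76,0.51,4.3,19.7,2.6
fpps,0.98,1.00,0.97,84.9,88.7,30.8
gcr,0.63,0.54,0.53,15.1,11.2,4.3
glcm,0.64,0.60,0.63,7.3,11,5.5
gria2,0.69,0.70,0.65,16.4,30,11.3
grik1,0.93,0.72,0.68,28.4,11.8,10.8
hdac2,0.89,0.46,0.47,18.7,5.3,5.9
hdac8,0.92,0.76,0.81,29.2,25.9,20.1
Hivint,0.70,0.44,0.55,14.3,2,4
Hivpr,0.69,0.68,0.68,5,6.1,7.1
Hivrt,0.78,0.62,0.60,17.7,12.7,9.3
Hmdh,0.88,0.88,0.89,34.3,51.2,37.3
hs90a,0.88,0.86,0.84,9.6,45.7,13.4
hxk4,0.45,0.82,0.88,4.3,37.6,30.1
igf1r,0.62,0.52,0.67,2,14.1,18.1
Inha,0.89,0.77,0.71,11.3,18.1,15.9
Ital,0.46,0.55,0.59,5.4,13,7.2
jak2,0.86,0.81,0.78,23.1,36.1,22.2
kif11,0.83,0.73,0.60,41.8,20.5,5.1
kit,0.50,0.45,0.28,3,3,1.2
kith,0.87,0.81,0.95,20.4,25.5,50.9
kpcb,0.80,0.77,0.68,36.3,47.6,34.6
lck,0.61,0.59,0.62,15.7,8.2,9.3
lkha4,0.89,0.81,0.81,13.9,31.3,27.2
mapk2,0.77,0.85,0.65,21.9,37.6,19.8
mcr,0.61,0.62,0.61,14.4,13.8,5.3
met,0.82,0.83,0.89,15.6,41.9,59.9
mk01,0.79,0.73,0.74,12.6,26,32.2
mk10,0.76,0.57,0.52,13.4,5.7,5.7
mk14,0.65,0.66,0.53,20.4,14.6,4
mmp13,0.73,0.80,0.75,10.4,25.2,20.3
mp2k1,0.58,0.47,0.44,2.5,14.8,4.9
nos1,0.75,0.42,0.49,8,2,2
nram,0.84,0.90,0.51,11.2,26.5,3.1
pa2ga,0.78,0.76,0.82,23.2,22,4
parp1,0.93,0.77,0.74,38.5,26.3,19.1
pde5a,0.80,0.62,0.70,13.6,26.7,26.7
pgh1,0.68,0.58,0.37,6.1,5.1,2
pgh2,0.73,0.79,0.68,11.4,36.7,21.3
plk1,0.89,0.60,0.56,33.9,1.9,0.9
pnph,0.98,0.94,0.97,56.7,55.7,63.4
ppara,0.82,0.87,0.75,16.9,27.4,15.3
ppard,0.77,0.74,0.51,12.4,12.4,4.2
pparg,0.82,0.80,0.67,18.2,19.7,21.9
prgr,0.81,0.71,0.62,25.7,9.2,0.7
ptn1,0.73,0.38,0.41,25.4,1.5,1.5
pur2,0.83,0.98,0.99,27.3,52.7,54.6
pygm,0.59,0.44,0.43,2.5,1.8,1.7
pyrd,0.87,0.88,0.70,50.1,48.3,47.4
reni,0.51,0.59,0.60,19.4,24.3,16.5
rock1,0.87,0.55,0.45,26.9,1,1
rxra,0.88,0.90,0.28,52.3,30.2,11.4
sahh,0.90,1.00,1.00,42.2,55.5,55.5
src,0.68,0.52,0.57,6.1,2.8,9.2
tgfr1,0.75,0.75,0.84,20.1,17.1,29
thb,0.87,0.89,0.78,39.8,59.5,25.9
thrb,0.70,0.55,0.51,13.3,2.5,1.4
try1,0.73,0.60,0.55,17.8,3.8,1.4
tryb1,0.77,0.51,0.60,15,4.1,5.4
tysy,0.73,0.78,0.81,23.6,19,27.2
urok,0.83,0.56,0.62,45.5,15.4,11.7
vgfr2,0.71,0.61,0.47,9.5,7.8,4.4
wee1,0.99,0.99,0.95,61,61,61.1
xiap,0.90,0.91,0.92,37.9,48.9,42
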