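# Reference characterization of narrow-leafed lupin genome regions carrying
# glutamine synthetase (GS) and phosphoenolpyruvate carboxylase (PEPC) genes:
# scaffold/linkage-group anchoring, GC content, repeat-masked content and
# gene counts (transcribed published values; packaged verification fixture).
gene_variant,family,scaffold,linkage_group,gc_percent,repeat_percent,repeat_bp,repeat_types,cds_count
GS1a1,GS,4_25,4,33.1,8.58,8584,Ty1/Copia,12
GS1a2,GS,106,16,32.94,15.63,15635,Ty1/Copia;Gypsy/DIRS1;DNA,10
GS1a3,GS,192,14,36.11,10.54,9282,Ty1/Copia;Gypsy/DIRS1;DNA,17
GS1b1,GS,73,11,33,0,0,-,15
GS1b2,GS,94_15,9,32.43,0.17,174,Ty1/Copia,16
GS1c1,GS,11_68,UN,30.56,9.19,2621,Ty1/Copia;DNA,3
GS1c2,GS,13,3,31.89,7.2,7202,Ty1/Copia;DNA,15
GS2a1,GS,45_213,19,33.88,9.96,9963,Ty1/Copia;Gypsy/DIRS1;DNA,12
GS2a2,GS,186,4,32.66,7.73,7732,Ty1/Copia;Gypsy/DIRS1;DNA,12
PEPC1a,PEPC,437,13,34.25,8.85,8852,Ty1/Copia;Gypsy/DIRS1,13
PEPC1b,PEPC,74_10,8,32.28,1.88,1879,Ty1/Copia,13
PEPC1c,PEPC,274,7,32.36,1.17,1169,Ty1/Copia,14
PEPC2a,PEPC,110_41,19,32.41,3.63,3634,Ty1/Copia;Gypsy/DIRS1,14
PEPC2b,PEPC,59_19,5,33.21,6.49,6748,Ty1/Copia;Gypsy/DIRS1,14
PEPC3a,PEPC,9_1,10,33.97,5.17,1628,Ty1/Copia,3
PEPC3b,PEPC,296,4,32.76,15.64,15641,Ty1/Copia;DNA,5
PEPC4,PEPC,12_32,7,33.76,8.64,8644,Ty1/Copia;Gypsy/DIRS1,16
PEPC5,PEPC,88_60,20,32.73,8.93,8933,Ty1/Copia;Gypsy/DIRS1;DNA,10
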