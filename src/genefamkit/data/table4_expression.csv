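# Normalized leaf expression of narrow-leafed lupin GS and PEPC paralogs in a
# recombinant inbred line population, with two reference genes (HEL, TUB)
# (transcribed published values; packaged verification fixture). GS2a2 was
# unannotated in the expression survey and has no values.
gene,family,accession,mean_expression,min_expression,max_expression,sd_expression
GS1a1,GS1,Lup021297,43.1,20.4,74.1,16.4
GS1a2,GS1,Lup001512,13.8,4.9,32.2,5.2
GS1a3,GS1,Lup009916,11.5,3.6,43.7,5.0
GS1b1,GS1,Lup029429,0.3,0.0,1.4,0.3
GS1b2,GS1,Lup032636,2.6,0.4,6.0,1.2
GS1c1,GS1,Lup002132,0.1,0.0,0.9,0.2
GS1c2,GS1,Lup004581,187.5,117.6,426.6,52.4
GS2a1,GS2,Lup023221,516.2,365.3,739.7,80.3
GS2a2,GS2,,,,,
PEPC1a,PEPC,Lup022696,17.0,8.1,31.1,4.0
PEPC1b,PEPC,Lup029825,0.5,0.0,2.4,0.5
PEPC1c,PEPC,Lup015178,65.0,44.5,87.4,8.7
PEPC2a,PEPC,Lup002214,0.0,0.0,0.5,0.1
PEPC2b,PEPC,Lup026946,0.1,0.0,0.9,0.2
PEPC3a,PEPC,Lup031846,10.5,4.7,16.1,2.5
PEPC3b,PEPC,Lup016482,51.0,33.0,94.2,11.2
PEPC4,PEPC,Lup002996,1.7,0.0,4.1,0.9
PEPC5,PEPC,Lup031638,11.9,1.7,28.7,4.8
HEL,reference,Lup023733,3.0,0.4,7.4,1.2
TUB,reference,Lup021845,78.4,35.3,113.1,15.2
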