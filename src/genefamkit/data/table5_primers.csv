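# Gene-specific primer pairs used for probe amplification against GS and PEPC
# (transcribed published values; packaged verification fixture).
probe,forward_primer,reverse_primer,product_length_bp,annealing_temperature_c
GS,GTTGGTCCCTCTGTTGGAATCTCTG,ATAAGCAGCAATGTGCTCATTGTGTCTC,571,56
PEPC,AAAGATGTTAGGAATCTTCACATGCTGCAAGA,GGGGCATATTCACTTGTTGGGTTCAGT,643,58
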