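# Selected taxon-specific qPCR assays with empirical specificity gaps and
# calibration parameters: Ct = a * log10(N) + b fitted on hand-picked
# nematode dilution series. delta_ct empty = no qPCR signal from any
# non-target. Guild codes: B bacterivore, F fungivore, FP facultative plant
# parasite, O omnivore, P predator. cp: colonizer-persister score (values for
# Dorylaimidae, Mononchidae and Mylonchulidae are the standard Bongers
# assignments; the survey text states the others).
assay,family,rank,guild,cp,delta_ct,a,b,r2,n_genera
Alaimidae,Alaimidae,family,B,4,,-3.31,25.47,0.996,1
Aphelenchidae,Aphelenchidae,family,"F,FP",2,42,-4.31,17.53,0.995,1
Aphelenchoididae,Aphelenchoididae,family,"F,FP",2,20,-3.06,24.09,0.992,1
Cephalobidae,Cephalobidae,family,B,2,17,-4.21,21.95,0.855,3
Diphtherophora,Diphtherophoridae,genus,F,3,18,-3.22,19.18,0.926,1
Tylolaimophorus,Diphtherophoridae,genus,F,3,,-3.02,22.36,0.984,1
Dorylaimidae,Dorylaimidae,family,O,4,,-5.90,17.30,0.859,1
Metateratocephalidae,Metateratocephalidae,family,B,3,26,-5.09,24.40,0.954,2
Monhysteridae,Monhysteridae,family,B,2,23,-4.25,21.06,0.954,1
Mononchidae,Mononchidae,family,P,4,18,-2.94,15.19,0.990,1
Mylonchulidae,Mylonchulidae,family,P,4,,-4.02,12.03,0.977,1
Plectidae_excl_Anaplectus,Plectidae,family,B,2,34,-1.93,26.82,0.989,1
Anaplectus,Plectidae,genus,B,2,27,-3.33,21.03,0.949,1
Prismatolaimidae,Prismatolaimidae,family,B,3,13,-5.13,21.64,0.999,1
Teratocephalidae,Teratocephalidae,family,B,3,,-4.41,25.13,0.999,1
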