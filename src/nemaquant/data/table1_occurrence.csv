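# Genus-level microscopy survey of the former arable field and adjacent beech
# forest topsoil (0-25 cm). qpcr: genus covered by a taxon-specific assay;
# range: quantitative calibration range available; plant_parasite: obligate
# plant parasite (excluded from the molecular analysis).
genus,family,qpcr,range,plant_parasite,field,forest
Achromadora,Achromadoridae,0,0,0,1,0
Acrobeles,Cephalobidae,1,1,0,1,0
Acrobeloides,Cephalobidae,1,0,0,1,1
Aglenchus,Tylenchidae,0,0,1,0,1
Alaimus,Alaimidae,1,1,0,1,1
Anaplectus,Plectidae,1,1,0,1,0
Aphelenchoides,Aphelenchoididae,1,1,0,1,1
Aphelenchus,Aphelenchidae,1,1,0,1,0
Aporcelaimellus,Aporcelaimidae,0,0,0,1,0
Bunonema,Bunonematidae,0,0,0,0,1
Cephalenchus,Tylodoridae,0,0,1,0,1
Cephalobus,Cephalobidae,1,0,0,1,0
Cervidellus,Cephalobidae,1,1,0,1,1
Clarkus,Mononchidae,1,1,0,1,0
Coomansus,Mononchidae,1,0,0,1,0
Coslenchus,Tylenchidae,0,0,1,0,1
Cylindrolaimus,Diplopeltidae,0,0,0,1,0
Diphtherophora,Diphtherophoridae,1,1,0,1,0
Ditylenchus,Anguinidae,0,0,1,1,1
Eucephalobus,Cephalobidae,1,1,0,1,1
Eudorylaimus,Qudsianematidae,0,0,0,0,1
Eumonhystera,Monhysteridae,1,1,0,1,1
Filenchus,Tylenchidae,0,0,1,1,1
Geomonhystera,Monhysteridae,0,0,0,1,0
Helicotylenchus,Hoplolaimidae,0,0,1,1,0
Malenchus,Tylenchidae,0,0,1,0,1
Meloidogyne,Meloidogynidae,0,0,1,1,0
Mesorhabditis,Mesorhabditidae,0,0,0,1,0
Metateratocephalus,Metateratocephalidae,1,1,0,1,1
Microdorylaimus,Qudsianematidae,0,0,0,1,0
Nygolaimus,Nygolaimidae,0,0,0,1,0
Panagrolaimus,Panagrolaimidae,0,0,0,1,0
Plectus,Plectidae,1,1,0,1,1
Pratylenchus,Pratylenchidae,0,0,1,1,0
Prismatolaimus,Prismatolaimidae,1,1,0,1,1
Pungentus,Nordiidae,0,0,0,1,0
Rhabditis,Rhabditidae,0,0,0,1,1
Steinernema,Steinernematidae,0,0,0,0,1
Teratocephalus,Teratocephalidae,1,1,0,1,1
Thonus,Dorylaimidae,1,1,0,1,1
Tylencholaimus,Tylencholaimidae,0,0,0,1,1
Tylenchorhynchus,Belonolaimidae,0,0,1,1,0
Tylenchus,Tylenchidae,0,0,1,1,1
Tylolaimophorus,Diphtherophoridae,1,1,0,1,1
Wilsonema,Plectidae,1,0,0,1,1
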