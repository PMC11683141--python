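# Illustrative functional trait database (bacterial genus -> plant-beneficial
# traits; fungal genus -> plant-pathogenic flag). Users supply their own.
taxon	kingdom	traits
Bacillus	bacteria	Bioc|PGP|SR
Pseudomonas	bacteria	Bioc|PGP|SR
Streptomyces	bacteria	Bioc|PGP
Burkholderia	bacteria	Bioc|PGP
Lysobacter	bacteria	Bioc
Collimonas	bacteria	Bioc
Rhizobium	bacteria	PGP
Mesorhizobium	bacteria	PGP
Devosia	bacteria	PGP
Arthrobacter	bacteria	PGP
Variovorax	bacteria	PGP|SR
Gemmatimonas	bacteria	SR
Sphingomonas	bacteria	SR
Fusarium	fungi	pathogenic
Volutella	fungi	pathogenic
Cadophora	fungi	pathogenic
Alternaria	fungi	pathogenic
Ilyonectria	fungi	pathogenic
Trichoderma	fungi	nonpathogenic
Mortierella	fungi	nonpathogenic
Penicillium	fungi	nonpathogenic
Chaetomium	fungi	nonpathogenic
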