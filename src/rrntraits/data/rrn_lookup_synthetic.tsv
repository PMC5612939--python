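genus	mean_copies
Phenylobacterium	1.0
Sphingomonas	2.0
Caulobacter	2.0
Acidovorax	3.0
Sphingobium	3.0
Flavobacterium	5.0
Azospirillum	9.0
Clostridium	9.0
Polaromonas	2.2
Rhodoferax	2.7
Novosphingobium	2.1
Methylibium	2.0
Hydrogenophaga	2.9
Rhizobium	3.1
Pedobacter	4.6
Duganella	5.4
Janthinobacterium	5.2
Pseudomonas	4.4
Acinetobacter	6.0
Aeromonas	9.8
Shewanella	8.7
Rheinheimera	7.1
Massilia	6.3
Arthrobacter	4.8
Exiguobacterium	7.6
Bacillus	9.9
Paenibacillus	10.6
Vibrio	11.1
Photobacterium	12.4
Lysinibacillus	12.8
Brevibacillus	13.5
Clostridium_sensu_stricto	14.6
Nitrospira	1.0
Gemmata	1.2
Planctomyces	1.4
Bradyrhizobium	1.3
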