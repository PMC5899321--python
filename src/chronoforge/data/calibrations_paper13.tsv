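clade_name	taxa	min_age	max_age	tail_prob
Chordata	Branchiostoma_lanceolatum,Homo_sapiens	519	581	0.025
Olfactores	Ciona_robusta,Homo_sapiens	519	581	0.025
Vertebrata	Petromyzon_marinus,Homo_sapiens	461	581	0.025
Gnathostomata	Callorhinchus_milii,Homo_sapiens	422	463	0.025
Osteichthyes	Danio_rerio,Homo_sapiens	416	422	0.025
Tetrapoda	Xenopus_tropicalis,Homo_sapiens	330	350	0.025
Amniota	Anolis_carolinensis,Homo_sapiens	312	330	0.025
Diapsida	Anolis_carolinensis,Gallus_gallus	256	300	0.025
Batrachia	Ambystoma_mexicanum,Xenopus_tropicalis	200	299	0.025
Clupeocephala	Danio_rerio,Takifugu_rubripes	150	165	0.025
Mammalia	Ornithorhynchus_anatinus,Homo_sapiens	163	191	0.025
Theria	Monodelphis_domestica,Homo_sapiens	124	171	0.025
Echinoidea	Paracentrotus_lividus,Strongylocentrotus_purpuratus	255		0.025
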