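# Fossil calibrations for the cetacean dating analysis (ages in Ma).
# Node anchors are (tip_a, tip_b) = MRCA designators; "root" fixes the root.
# Hard bounds have zero tail probability; soft bounds carry the listed tail.
tip_a	tip_b	t_min_Ma	min_type	t_max_Ma	max_type	pL	pU	node_label
root	root	52.40	hard	164.6	soft	0	0.025	Perissodactyla+Cetartiodactyla
Camelus_bactrianus	Orcinus_orca	52.40	hard	66.00	soft	0	0.025	Crown_Cetartiodactyla
Bos_taurus	Orcinus_orca	52.40	hard	66.00	soft	0	0.025	Cetruminantia
Hippopotamus_amphibius	Orcinus_orca	52.40	hard	66.00	soft	0	0.025	Whippomorpha
Bos_taurus	Ovis_aries	16.00	hard	28.00	soft	0	0.025	Crown_Bovidae
Balaenoptera_acutorostrata	Orcinus_orca	36.40	hard	52.40	soft	0	0.025	Crown_Cetacea
Balaenoptera_acutorostrata	Balaena_mysticetus	25.20	hard	36.40	soft	0	0.025	Crown_Mysticeti
Ziphius_cavirostris	Berardius_bairdii	13.20	hard	23.00	soft	0	0.025	Crown_Ziphiidae
Phocoena_phocoena	Delphinapterus_leucas	7.50	hard	19.50	soft	0	0.025	Phocoenidae+Monodontidae
Orcinus_orca	Tursiops_truncatus	8.5	hard	19.50	soft	0	0.025	Delphinidae_excl_L_albirostris
Tursiops_truncatus	Stenella_attenuata	3.98	hard	8.5	soft	0	0.025	Delphininae_excl_S_guianensis
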