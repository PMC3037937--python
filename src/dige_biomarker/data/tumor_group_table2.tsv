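gene	protein	log10_p
EIF4A3	Eukaryotic initiation factor 4A-III	-9.7068
RPSA	40S ribosomal protein SA	-8.2847
ACTG1	Actin, cytoplasmic 2	-8.2063
PPP1CA	Serine/threonine-protein phosphatase PP1-alpha catalytic subunit	-7.9832
HSPA5	78 kDa glucose-regulated protein	-7.8941
HSP90B1	Endoplasmin	-7.836
EEF1G	Elongation factor 1-gamma	-7.7305
Albu	Serum albumin	-7.4314
TALDO	Transaldolase	-6.9937
CRYL1	Lambda-crystallin homolog	-6.917
GSTP1	Glutathione S-transferase P	-6.7989
HSP90AB1	Endoplasmin	-6.5476
NDRG1	Protein NDRG1	-6.1405
ACPP	Prostatic acid phosphatase	-6.0939
PDIA3	Protein disulfide-isomerase A3	-5.9345
PDIA3	Protein disulfide-isomerase A3	-5.8639
DPYSL2	Dihydropyrimidinase-related protein 2	-5.7179
PDIA3	Protein disulfide-isomerase A3	-5.6059
PSMD	26S proteasome non-ATPase regulatory subunit 14	-5.5825
PPA2	Inorganic pyrophosphatase 2, mitochondrial	-5.5641
Albu	Serum albumin	-5.5566
NDUFS1	NADH-ubiquinone oxidoreductase 75 kDa subunit, mitochondrial	-5.4327
C7orf24	Uncharacterized protein C7orf24	-5.2732
DDAH1	N(G),N(G)-dimethylarginine dimethylaminohydrolase 1	-5.2715
P4HB	Protein disulfide-isomerase	-5.1191
PGLS	6-phosphogluconolactonase	-5.0895
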