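pathway	declared_size	genes
Gluconeogenesis	9	PC, PCK1, PCK2, *FBP1, FBP2, G6PC1, G6PC2, G6PC3, PFKFB2
Glycolysis	27	HK1, HK2, HK3, GCK, GPI, *PFKL, *PFKM, *PFKP, ALDOA, ALDOB, ALDOC, TPI1, GAPDH, GAPDHS, PGK1, PGK2, BPGM, PGAM1, PGAM2, PGAM4, ENO1, ENO2, ENO3, ENO4, PKLR, PKM
Lactate Shuttle (Neuron-Astrocyte)	18	SLC2A3, *LDHA, LDHC, LDHD, SLC16A1, SLC16A3, GLS, GLS2, GLUL, SLC2A1, SLC2A10, SLC2A11, SLC2A12, SLC2A14, SLC1A1, SLC1A2, SLC1A3, SLC1A6
Tricarboxylic Acid (TCA) Cycle	30	*CS, ACLY, ACO1, ACO2, IREB2, IDH1, IDH2, IDH3A, IDH3B, IDH3G, OGDH, OGDHL, SUCLA2, SUCLG2, SUCLG1, SDHA, SDHB, SDHC, SDHD, SDHAF1, SDHAF4, ALDH5A1, FH, MDH1B, MDH2, PDHA1, PDHA2, DBT, DLAT, DLD
Electron Transport Chain (ETC)	69	NDUFA8, NDUFS4, NDUFV3, NDUFA11, NDUFS5, NDUFC1, NDUFC2, NDUFS1, NDUFV2, NDUFV1, NDUFA12, NDUFB5, MT-ND1, MT-ND2, MT-ND3, MT-ND4, MT-ND5, MT-ND6, MT-ND4L, SDHA, SDHB, SDHC, SDHD, SDHAF1, SDHAF2, SDHAF3, SDHAF4, UQCRB, UQCRQ, UQCRC1, UQCRC2, UQCR10, MT-CYB, CYC1, UQCRFS1, UQCRH, UQCR10, UQCR11, *COX4I1, *COX4I2, *COX5A, *COX5B, *COX6A1, *COX6A2, *COX6B1, *COX6B2, *COX6C, *COX7A1, *COX7A2, *COX7B, *COX7B2, *COX7C, *COX8A, *COX8C, *MT-CO1, *MT-CO2, *MT-CO3, COQ4, COQ7, COQ10A, COQ10B, CYCS, ATP5F1A, ATP5F1B, ATP5F1C, ATP5F1D, ATP5F1E, MT-ATP6, MT-ATP8
Fatty Acid Synthesis	13	*ACACA, ACACB, MCAT, FASN, OXSM, DECR1, HADH, ELOVL1, ELOVL3, ELOVL6, OLAH, PPT1, PPT2
Fatty Acid Oxidation	17	SLC27A2, ACSBG2, ACSBG1, ECI1, ECHS1, HADHA, HSD17B10, HADH, HADHB, ACAA2, SCP2, VLCAD, SCAD, MCAD, LCAD, *CPT1C, CPT2
Ketogenesis	9	ACAT1, ACAA1, ACAA2, *HMGCS1, HMGCS2, HMGCL, HMGCLL1, BDH2, BDH1
Glycogenesis	13	ADPGK, GCKR, HK1, HK2, HK3, PGM1, PGM2, UGP2, *GYS1, *GYS2, GSK3A, GSK3B, GBE1
Glycogenolysis	9	*PYGL, *PYGM, PYGB, AGL, PGM1, PGM2, G6PC1, G6PC2, G6PC3
Urea Cycle	11	OTC, OAT, *CPS1, CAD, ASS1, ASL, ARG1, ARG2, AGMAT, NAGS, ACY1
Pentose Phosphate/Glutathione Pathways	17	HK1, HK2, HK3, *G6PD, PGD, TKT, TKTL1, TKTL2, TALDO1, GPI, GCLC, GSS, GSR, SOD1, RPE, RPIA, RGN
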