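# 4-letter code	species name
HSAP	Homo_sapiens
MMUS	Mus_musculus
TRUB	Takifugu_rubripes
DRER	Danio_rerio
CINT	Ciona_intestinalis
BFLO	Branchiostoma_floridae
CELE	Caenorhabditis_elegans
DMEL	Drosophila_melanogaster
AGAM	Anopheles_gambiae
NVEC	Nematostella_vectensis
TADH	Trichoplax_adhaerens
MBRE	Monosiga_brevicollis
BDEN	Batrachochytrium_dendrobatidis
NCRA	Neurospora_crassa
YLIP	Yarrowia_lipolytica
DHAN	Debaryomyces_hansenii
KLAC	Kluyveromyces_lactis
CGLA	Candida_glabrata
SCER	Saccharomyces_cerevisiae
SPOM	Schizosaccharomyces_pombe
CNEO	Cryptococcus_neoformans
UMAY	Ustilago_maydis
PBLA	Phycomyces_blakesleeanus
RORY	Rhizopus_oryzae
ECUN	Encephalitozoon_cuniculi
EHIS	Entamoeba_histolytica
DDIS	Dictyostelium_discoideum
PFAL	Plasmodium_falciparum
CPAR	Cryptosporidium_parvum
TGON	Toxoplasma_gondii
TTHE	Tetrahymena_thermophila
PTET	Paramecium_tetraurelia
PINF	Phytophthora_infestans
PSOJ	Phytophthora_sojae
PTRI	Phaeodactylum_tricornutum
TPSE	Thalassiosira_pseudonana
EHUX	Emiliania_huxleyi
PPAT	Physcomitrella_patens
ATHA	Arabidopsis_thaliana
OSAT	Oryza_sativa
SMOE	Selaginella_moellendorffii
CREI	Chlamydomonas_reinhardtii
VCAR	Volvox_carteri
MPUS	Micromonas_pusilla
OTAU	Ostreococcus_tauri
CMER	Cyanidioschyzon_merolae
LMAJ	Leishmania_major
TBRU	Trypanosoma_brucei
GINT	Giardia_intestinalis
NGRU	Naegleria_gruberi
TVAG	Trichomonas_vaginalis
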