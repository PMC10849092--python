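# Synthetic approximation of a 14-group taxonomy over the green lineage,
# reconstructed from publicly listed strain names. Replace with your own
# two-column table (taxon<TAB>group) for real analyses.
Chlamydomonas_reinhardtii	chlorophytes
Chlorella_vulgaris	chlorophytes
Coccomyxa_subellipsoidea	chlorophytes
Ulva_mutabilis	chlorophytes
Mesostigma_viride	mesostigmatophytes
Chlorokybus_cerffii	chlorokybophytes
Klebsormidium_nitens	klebsormidium
Klebsormidium_flaccidum	klebsormidium
Klebsormidium_crenulatum	klebsormidium
Klebsormidium_subtile	klebsormidium
Klebsormidium_dissectum	klebsormidium
Klebsormidium_elegans	klebsormidium
Klebsormidium_mucosum	klebsormidium
Klebsormidium_africanum	klebsormidium
Klebsormidium_deserticola	klebsormidium
Interfilum_paradoxum	interfilum_streptofilum
Interfilum_terricola	interfilum_streptofilum
Interfilum_massjukiae	interfilum_streptofilum
Streptofilum_capillatum	interfilum_streptofilum
Hormidiella_parvula	hormidiella
Streptosarcina_arenaria	streptosarcina
Streptosarcina_costaricana	streptosarcina
Entransia_fimbriata	entransia
Chara_braunii	charophyceae
Nitella_mirabilis	charophyceae
Coleochaete_orbicularis	coleochaetophyceae
Coleochaete_scutata	coleochaetophyceae
Chaetosphaeridium_globosum	coleochaetophyceae
Zygnema_circumcarinatum	zygnematophyceae
Spirogyra_pratensis	zygnematophyceae
Mougeotia_sp	zygnematophyceae
Mesotaenium_endlicherianum	zygnematophyceae
Spirogloea_muscicola	zygnematophyceae
Physcomitrium_patens	bryophytes
Marchantia_polymorpha	bryophytes
Anthoceros_agrestis	bryophytes
Isoetes_taiwanensis	lycophytes_ferns
Azolla_filiculoides	lycophytes_ferns
Arabidopsis_thaliana	angiosperms
Brachypodium_distachyon	angiosperms
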