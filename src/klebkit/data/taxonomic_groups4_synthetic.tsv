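# Synthetic 4-group scheme for post-pruning filtering:
# chlorophytes / non-klebsormidiophycean streptophytes / Klebsormidium /
# other Klebsormidiophyceae. Replace with your own table for real analyses.
Chlamydomonas_reinhardtii	chlorophytes
Chlorella_vulgaris	chlorophytes
Coccomyxa_subellipsoidea	chlorophytes
Ulva_mutabilis	chlorophytes
Mesostigma_viride	non_kleb_streptophytes
Chlorokybus_cerffii	non_kleb_streptophytes
Chara_braunii	non_kleb_streptophytes
Nitella_mirabilis	non_kleb_streptophytes
Coleochaete_orbicularis	non_kleb_streptophytes
Coleochaete_scutata	non_kleb_streptophytes
Chaetosphaeridium_globosum	non_kleb_streptophytes
Zygnema_circumcarinatum	non_kleb_streptophytes
Spirogyra_pratensis	non_kleb_streptophytes
Mougeotia_sp	non_kleb_streptophytes
Mesotaenium_endlicherianum	non_kleb_streptophytes
Spirogloea_muscicola	non_kleb_streptophytes
Physcomitrium_patens	non_kleb_streptophytes
Marchantia_polymorpha	non_kleb_streptophytes
Anthoceros_agrestis	non_kleb_streptophytes
Isoetes_taiwanensis	non_kleb_streptophytes
Azolla_filiculoides	non_kleb_streptophytes
Arabidopsis_thaliana	non_kleb_streptophytes
Brachypodium_distachyon	non_kleb_streptophytes
Klebsormidium_nitens	klebsormidium
Klebsormidium_flaccidum	klebsormidium
Klebsormidium_crenulatum	klebsormidium
Klebsormidium_subtile	klebsormidium
Klebsormidium_dissectum	klebsormidium
Klebsormidium_elegans	klebsormidium
Klebsormidium_mucosum	klebsormidium
Klebsormidium_africanum	klebsormidium
Klebsormidium_deserticola	klebsormidium
Interfilum_paradoxum	other_klebsormidiophyceae
Interfilum_terricola	other_klebsormidiophyceae
Interfilum_massjukiae	other_klebsormidiophyceae
Streptofilum_capillatum	other_klebsormidiophyceae
Hormidiella_parvula	other_klebsormidiophyceae
Streptosarcina_arenaria	other_klebsormidiophyceae
Streptosarcina_costaricana	other_klebsormidiophyceae
Entransia_fimbriata	other_klebsormidiophyceae
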