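((Aphrodita_aculeate,Palmyra_aurifera),((Pholoe_baltica,Pholoe_pallida),(Harmothoe_rarispina,((Neoleanira_tetragona,Euthalenessa_cf_digitata),(Sigalion_spinosus,((Pisionidens_ixazaluohae,Pisionidens_sp),((Pisione_guanche,(Pisione_remota,(Pisione_puzae_Napoli,Pisione_puzae_Sicily,Pisione_cf_puzae_Galicia))),((Pisione_cf_vestigalis,Pisione_spA),(Pisione_papuensis,(Pisione_bulbifera,((Pisione_wolfi_Caletones,Pisione_wolfi_Trinidad),(Pisione_hartmannschroederae_CayoGuillermo,Pisione_hartmannschroederae_Miramar,Pisione_hartmannschroederae_Belize,Pisione_hartmannschroederae_Noronha,Pisione_hartmannschroederae_Chivirico))))))))))));
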