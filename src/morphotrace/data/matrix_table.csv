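Aphrodita_aculeate,1,0,0,1,0,1,0,1,1,1,0,1,2,1,1,0,0,0,0,0,0,0,0,1,1,1,0,0,0,1,0,0,0,-,-,-,-,-,-,-,-,-,-,-
Palmyra_aurifera,2,0,0,1,0,1,0,1,1,1,0,1,2,0,1,0,0,0,0,0,0,0,0,?,1,0,0,0,0,0,0,1,0,-,-,-,-,-,-,-,-,-,-,-
Pholoe_baltica,0,0,0,1,?,0,1,1,1,0,0,0,-,?,1,0,0,0,0,0,1,1,0,1,0,0,1,1,0,1,0,1,0,-,-,0,-,-,-,-,-,-,-,-
Pholoe_pallida,0,0,0,1,0,0,0,1,0,0,0,0,-,1,1,0,0,0,0,0,1,1,0,1,0,0,1,1,0,1,0,1,0,-,-,0,-,-,-,-,-,-,-,-
Harmothoe_rarispina,1,0,0,1,1,0,1,1,1,0,0,1,2,1,1,0,0,0,0,0,?,0,0,1,1,1,0,0,0,1,0,1,0,-,0,-,-,-,-,-,-,-,-,-
Neoleanira_tetragona,0,1,1,1,1,1,0,1,0,1,0,1,0,1,1,0,1,1,0,0,1,1,0,1,0,0,0,0,1,1,0,0,0,-,-,1,-,-,-,-,-,-,-,-
Euthalenessa_cf_digitata,0,1,1,1,1,0,0,1,1,1,0,1,0,1,1,0,1,1,0,0,1,1,0,1,0,0,0,1,0,1,0,0,0,-,-,1,-,-,-,-,-,-,-,-
Pisionidens_ixazaluohae,0,0,0,0,1,0,0,0,1,0,0,1,3,0,0,1,0,1,1,1,1,1,0,0,-,-,-,-,-,0,1,0,-,1,-,-,0,0,1,1,1,0,0,0
Pisionidens_sp,0,0,0,0,1,0,0,0,1,0,0,1,3,0,0,1,0,1,1,1,1,1,0,0,?,-,-,-,-,0,1,0,-,1,-,-,?,?,?,?,?,?,?,?
Pisione_bulbifera,3,1,1,0,0,0,1,1,1,0,1,1,3,0,1,0,0,1,1,1,1,1,1,0,1,1,1,1,1,0,0,0,0,0,1,1,0,0,0,0,0,0,1,0
Pisione_guanche,3,1,1,0,0,0,1,1,1,0,1,1,3,0,1,0,0,1,1,1,1,1,1,0,1,1,1,1,1,0,0,1,0,1,0,0,0,?,1,1,1,0,0,0
Pisione_hartmannschroederae_CayoGuillermo,3,1,1,0,0,0,1,1,1,0,1,1,3,0,1,0,0,1,1,1,1,1,0,0,1,1,1,1,1,0,0,0,0,1,1,1,0,0,0,0,0,1,1,0
Pisione_hartmannschroederae_Miramar,3,?,?,0,0,0,1,1,1,0,1,1,3,0,1,0,0,1,1,1,1,1,1,0,1,1,1,1,1,0,0,0,0,0,0,1,?,?,?,?,?,?,?,?
Pisione_hartmannschroederae_Belize,3,1,1,0,0,0,1,1,1,0,1,1,3,0,1,0,0,1,1,1,1,1,0,0,1,1,1,1,1,0,0,0,0,1,1,1,0,0,0,0,0,1,1,0
Pisione_hartmannschroederae_Noronha,3,1,1,0,0,0,1,1,1,0,1,1,3,0,1,0,0,1,1,1,1,1,?,0,1,1,1,1,1,0,0,?,?,?,?,?,?,?,?,?,?,?,?,?
Pisione_hartmannschroederae_Chivirico,3,1,1,0,0,0,1,1,1,0,1,1,3,0,1,0,0,1,1,1,1,1,?,0,1,1,1,1,1,0,0,?,?,?,?,?,?,?,?,?,?,?,?,?
Pisione_papuensis,3,?,?,0,0,0,1,1,1,0,1,1,3,0,1,0,0,1,1,1,1,1,0,0,1,1,1,1,1,0,0,0,0,1,1,1,2,1,0,0,0,0,0,1
Pisione_puzae_Napoli,3,1,1,0,0,0,1,1,1,0,1,1,3,0,1,0,0,1,1,1,1,1,1,0,1,1,1,1,1,0,0,0,1,0,0,0,0,1,0,1,?,?,1,0
Pisione_puzae_Sicily,3,1,1,0,0,0,1,1,1,0,1,1,3,0,1,0,0,1,1,1,1,1,0,0,1,1,1,1,1,0,0,0,0,1,1,1,?,1,1,1,1,1,1,0
Pisione_cf_puzae_Galicia,3,1,1,0,0,0,1,1,1,0,1,1,3,0,1,0,0,1,1,1,1,1,?,0,1,1,1,1,1,0,0,0,1,0,0,0,0,1,0,1,?,?,1,0
Pisione_remota,3,1,1,0,0,0,1,1,1,0,1,1,3,0,1,0,0,1,1,1,1,1,1,0,1,1,1,1,1,0,0,0,1,0,0,0,0,1,0,1,1,1,1,0
Pisione_spA,?,?,?,0,0,0,1,1,1,0,?,1,3,0,1,0,0,1,1,1,1,1,?,0,1,1,?,1,1,0,0,0,1,0,0,0,0,1,1,0,1,1,1,0
Pisione_wolfi_Caletones,3,1,0,0,0,0,1,1,1,0,1,1,3,0,1,0,0,1,1,1,1,1,0,0,1,1,1,1,1,0,0,0,0,0,1,1,0,1,1,1,0,0,1,0
Pisione_wolfi_Trinidad,3,1,1,0,0,0,1,1,1,0,1,1,3,0,1,0,0,1,1,1,1,1,?,0,1,1,1,1,1,0,0,0,0,0,1,1,0,1,1,1,0,0,1,0
Pisione_cf_vestigalis,3,1,1,0,0,0,1,1,1,0,1,1,3,0,1,0,0,1,1,1,1,1,1,0,1,1,1,1,1,0,0,0,1,0,1,0,0,1,1,0,1,1,1,0
Sigalion_spinosus,0,0,0,?,?,0,0,1,1,?,0,0,-,?,1,0,0,0,0,0,1,1,0,1,?,0,0,1,0,1,0,?,0,-,-,1,-,-,-,-,-,-,-,-
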