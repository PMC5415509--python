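species,max_copulatory_organs,complexity,max_body_length,max_segments,region
Pisione_guanche,2,3,4.0,45,Eastern Atlantic
Pisione_remota,3,5,6.0,60,Eastern Atlantic
Pisione_puzae_Napoli,2,3,5.0,55,Eastern Atlantic
Pisione_bulbifera,3,1,5.5,58,Indo-Pacific
Pisione_papuensis,4,2,7.0,66,Indo-Pacific
Pisione_hartmannschroederae_CayoGuillermo,12,2,9.0,78,Western Atlantic
Pisione_wolfi_Caletones,10,4,8.0,72,Western Atlantic
Pisione_spA,15,5,10.0,85,Indo-Pacific
Pisione_cf_vestigalis,14,5,9.5,80,Indo-Pacific
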