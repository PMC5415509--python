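species,lat,lon
Pisione_bulbifera,29.544234,34.957981
Pisione_guanche,29.155104,-13.427786
Pisione_hartmannschroederae,22.602347,-78.666218
Pisione_hartmannschroederae,19.982876,-75.866531
Pisione_hartmannschroederae,16.80226,-88.081755
Pisione_hartmannschroederae,-3.847415,-32.437092
Pisione_hartmannschroederae,19.968616,-76.408428
Pisione_papuensis,-21.917467,152.588242
Pisione_puzae,40.577043,14.329735
Pisione_puzae,37.029597,15.318359
Pisione_cf_puzae,43.488092,-8.322003
Pisione_remota,58.268694,11.410536
Pisione_spA,-8.454662,144.439866
Pisione_wolfi,21.210457,-76.242444
Pisione_wolfi,21.766186,-79.986889
Pisione_cf_vestigalis,-0.282247,-90.548478
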