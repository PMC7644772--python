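name	lat	lon	species
Irogno Forest	-14.7491	48.4914	ambreensis
Sahaovy, Makira Reserve	-15.4889	49.0785	ambreensis
Camp Norbert, Manongarivo	-13.9481	48.4578	ambreensis
Maromiandra	-13.9965	48.2177	ambreensis
Tsaratanana Massif	-14.0422	48.7617	ambreensis
Montagne d'Ambre	-12.4900	49.1719	ambreensis
Foret d'Ambre	-12.4753	49.2142	ambreensis
Bevintagnona Forest	-14.7385	48.5170	ambreensis
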