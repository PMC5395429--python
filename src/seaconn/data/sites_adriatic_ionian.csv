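acronym,lon,lat
OTH,19.935636,39.793289
KAP,19.324967,40.392800
BOK,18.569633,42.387533
KOR,15.281483,43.792250
TRE,15.523950,42.138583
TOG,17.800050,40.716650
OTR,18.519217,40.109233
POC,17.917950,40.195250
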