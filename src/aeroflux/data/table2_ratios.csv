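day,virus_aerosol_bulk,bacteria_aerosol_bulk
4,0.54,11.39
7,0.62,9.75
9,1.11,3.65
11,1.13,8.87
18,0.48,16.30
20,0.07,11.56
22,0.07,1.42
average,0.68,11.13
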