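entity,compartment,day,value,sd
virus_particles,bulk,4,1.86,0.40
virus_particles,bulk,5,1.00,0.29
virus_particles,bulk,6,2.17,0.52
virus_particles,bulk,7,1.68,0.32
virus_particles,bulk,8,0.60,0.10
virus_particles,bulk,9,1.93,0.21
virus_particles,bulk,10,1.10,0.38
virus_particles,bulk,11,1.01,0.23
virus_particles,bulk,12,1.24,0.27
virus_particles,bulk,13,1.63,0.34
virus_particles,bulk,14,1.44,0.26
virus_particles,bulk,15,1.72,0.33
virus_particles,bulk,16,2.99,0.36
virus_particles,bulk,17,2.36,0.26
virus_particles,bulk,18,2.91,0.42
virus_particles,bulk,20,4.56,0.43
virus_particles,bulk,21,4.36,0.36
virus_particles,bulk,22,7.97,0.79
virus_particles,bulk,23,4.76,0.65
virus_particles,bulk,24,3.63,0.52
virus_particles,bulk,25,8.01,0.80
virus_particles,bulk,26,5.50,0.74
virus_particles,bulk,27,5.07,0.59
virus_particles,bulk,28,5.26,0.62
virus_particles,ssml,7,1.32,0.19
virus_particles,ssml,8,1.21,0.22
virus_particles,ssml,9,1.21,0.22
virus_particles,ssml,10,1.43,0.28
virus_particles,ssml,16,2.08,0.27
virus_particles,ssml,17,3.54,0.42
virus_particles,ssml,18,3.85,0.51
virus_particles,ssml,20,3.66,0.57
virus_particles,ssml,21,3.90,0.42
virus_particles,ssml,22,3.04,0.43
virus_particles,ssml,23,3.66,0.35
virus_particles,ssml,24,3.96,0.53
virus_particles,ssml,29,5.56,0.92
virus_particles,ssml,32,1.59,0.54
virus_particles,ssml,33,2.35,0.54
virus_particles,ssml,34,3.48,0.68
virus_particles,ssml,35,4.06,0.49
virus_particles,ssml,36,2.95,0.34
virus_particles,aerosol,0,1.58,0.18
virus_particles,aerosol,1,0.70,0.08
virus_particles,aerosol,2,0.77,0.09
virus_particles,aerosol,4,1.01,0.11
virus_particles,aerosol,6,2.33,0.26
virus_particles,aerosol,7,1.04,0.12
virus_particles,aerosol,9,2.14,0.24
virus_particles,aerosol,11,1.14,0.13
virus_particles,aerosol,13,1.20,0.13
virus_particles,aerosol,14,1.32,0.15
virus_particles,aerosol,18,1.39,0.15
virus_particles,aerosol,20,0.33,0.04
virus_particles,aerosol,22,0.55,0.06
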