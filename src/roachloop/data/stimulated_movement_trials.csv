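animal,trial,search_rate,distance,central_rate,peripheral_rate,stop_time,stimulation_time
C1,1,0.44,27.37,0.08,0.92,112.53,4.64
C1,2,0.59,32.166,0.22,0.78,87.49,2.35
C1,3,0.62,33.17,0.25,0.75,52.12,1.47
C2,1,0.41,24.39,0.05,0.95,11.26,5.67
C2,2,0.51,37.02,0.20,0.80,11.26,1.91
C2,3,0.37,40.18,0.03,0.97,10.39,1.14
C3,1,0.53,34.60,0.19,0.81,118.40,10.13
C3,2,0.80,48.95,0.46,0.54,11.36,0.88
C3,3,0.83,74.29,0.35,0.65,33.20,2.74
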