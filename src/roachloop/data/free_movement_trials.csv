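animal,trial,search_rate,distance,central_rate,peripheral_rate,stop_time
C1,1,0.10,5.47,0.06,0.94,392.02
C1,2,0.15,9.56,0.17,0.83,342.99
C1,3,0.20,12.63,0.30,0.70,330.02
C2,1,0.01,7.63,1.00,0.00,420
C2,2,0.39,18.54,0.31,0.69,126.85
C2,3,0.72,46.00,0.47,0.53,86.01
C3,1,0.07,10.75,0.69,0.31,379.41
C3,2,0.70,50.23,0.20,0.80,20.48
C3,3,0.67,48.23,0.21,0.79,27.78
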