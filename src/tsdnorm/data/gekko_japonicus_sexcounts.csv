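population,temperature_C,n_female,n_male,n_unidentified
Yancheng,24,47,12,0
Yancheng,26,44,25,2
Yancheng,28,16,44,1
Yancheng,30,29,42,2
Yancheng,32,39,10,0
Chuzhou,24,22,3,0
Chuzhou,26,25,12,3
Chuzhou,28,8,13,0
Chuzhou,30,7,20,2
Chuzhou,32,17,1,0
Wenzhou,24,41,8,3
Wenzhou,26,34,44,6
Wenzhou,28,24,24,1
Wenzhou,30,43,46,0
Wenzhou,32,51,18,1
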