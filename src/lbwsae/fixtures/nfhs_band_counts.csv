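group,count_1,count_2,count_3,count_4,count_5,count_6,count_7
India,92,78,140,145,135,68,62
North,34,19,19,22,17,8,17
North-East,3,8,29,28,20,9,7
South,22,21,35,27,24,5,7
East,5,8,19,20,28,19,13
West,7,8,14,20,11,10,4
Central,21,14,24,28,35,17,14
ADP,15,10,18,29,21,12,12
non-ADP,77,68,122,116,114,56,50
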