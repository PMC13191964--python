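region,prevalence_2021_pct,prevalence_2016_pct
India,18.24,18.21
North,18.71,20.76
North-East,14.93,14.69
South,16.04,16.65
East,17.61,16.19
West,19.48,19.37
Central,19.88,20.09
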