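district_id
Andaman & Nicobar Islands::d002
Andaman & Nicobar Islands::d004
Andaman & Nicobar Islands::d006
Andaman & Nicobar Islands::d011
Andaman & Nicobar Islands::d015
Andaman & Nicobar Islands::d019
Andhra Pradesh::d002
Andhra Pradesh::d005
Andhra Pradesh::d014
Arunachal Pradesh::d002
Arunachal Pradesh::d006
Arunachal Pradesh::d010
Arunachal Pradesh::d012
Arunachal Pradesh::d017
Arunachal Pradesh::d019
Bihar::d001
Bihar::d011
Chandigarh::d008
Chandigarh::d012
Dadra & Nagar Haveli::d019
Goa::d004
Goa::d008
Goa::d010
Goa::d014
Goa::d015
Gujarat::d004
Gujarat::d008
Gujarat::d013
Haryana::d010
Himachal Pradesh::d002
Himachal Pradesh::d004
Himachal Pradesh::d008
Himachal Pradesh::d014
Himachal Pradesh::d020
Jammu & Kashmir::d005
Jammu & Kashmir::d008
Jammu & Kashmir::d011
Jammu & Kashmir::d012
Jammu & Kashmir::d014
Jammu & Kashmir::d020
Jharkhand::d005
Jharkhand::d012
Karnataka::d003
Karnataka::d006
Kerala::d003
Kerala::d009
Kerala::d010
Kerala::d011
Ladakh::d003
Ladakh::d009
Ladakh::d018
Lakshadweep::d002
Lakshadweep::d006
Lakshadweep::d009
Lakshadweep::d010
Lakshadweep::d014
Madhya Pradesh::d003
Madhya Pradesh::d015
Maharashtra::d006
Maharashtra::d008
Maharashtra::d012
Maharashtra::d013
Maharashtra::d019
Manipur::d002
Manipur::d010
Manipur::d020
Meghalaya::d002
Meghalaya::d012
Meghalaya::d016
Mizoram::d012
Mizoram::d014
Mizoram::d018
NCT Of Delhi::d001
NCT Of Delhi::d002
NCT Of Delhi::d009
NCT Of Delhi::d018
Nagaland::d004
Nagaland::d005
Nagaland::d008
Nagaland::d016
Nagaland::d019
Nagaland::d020
Odisha::d008
Odisha::d010
Odisha::d014
Puducherry::d007
Puducherry::d010
Puducherry::d017
Puducherry::d020
Punjab::d010
Punjab::d015
Punjab::d018
Rajasthan::d001
Rajasthan::d002
Rajasthan::d009
Rajasthan::d013
Sikkim::d003
Sikkim::d005
Sikkim::d006
Sikkim::d020
Tamil Nadu::d004
Tamil Nadu::d016
Tamil Nadu::d019
Telangana::d002
Telangana::d009
Telangana::d017
Tripura::d003
Tripura::d007
Tripura::d016
Uttar Pradesh::d007
Uttarakhand::d010
Uttarakhand::d013
Uttarakhand::d018
Uttarakhand::d019
West Bengal::d010
West Bengal::d014
West Bengal::d015
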