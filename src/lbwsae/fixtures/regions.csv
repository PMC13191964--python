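state,region
Jammu & Kashmir,North
Himachal Pradesh,North
Punjab,North
Chandigarh,North
Uttarakhand,North
Haryana,North
NCT Of Delhi,North
Rajasthan,North
Ladakh,North
Sikkim,North-East
Arunachal Pradesh,North-East
Nagaland,North-East
Manipur,North-East
Mizoram,North-East
Tripura,North-East
Meghalaya,North-East
Assam,North-East
Karnataka,South
Lakshadweep,South
Kerala,South
Tamil Nadu,South
Puducherry,South
Andaman & Nicobar Islands,South
Telangana,South
Andhra Pradesh,South
Bihar,East
West Bengal,East
Jharkhand,East
Odisha,East
Gujarat,West
Dadra & Nagar Haveli,West
Maharashtra,West
Goa,West
Chhattisgarh,Central
Madhya Pradesh,Central
Uttar Pradesh,Central
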