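generic_name,moa_class,duration_type,atc_code,max_days_per_rx
Flurazepam,BZD,long,N05CD01,30
Quazepam,BZD,long,N05CD10,30
Haloxazolam,BZD,long,,30
Nitrazepam,BZD,intermediate,N05CD02,90
Flunitrazepam,BZD,intermediate,N05CD03,30
Estazolam,BZD,intermediate,N05CD04,30
Nimetazepam,BZD,intermediate,,30
Lormetazepam,BZD,short,N05CD06,30
Brotizolam,BZD,short,N05CD09,30
Etizolam,BZD,short,N05BA19,30
Rilmazafone hydrochloride,BZD,short,,
Triazolam,BZD,ultrashort,N05CD05,30
Zopiclone,Z_DRUG,ultrashort,N05CF01,30
Zolpidem tartrate,Z_DRUG,ultrashort,N05CF02,30
Eszopiclone,Z_DRUG,ultrashort,N05CF04,
Ramelteon,MRA,,N05CH02,
Suvorexant,ORA,,N05CM19,
Phenobarbital,OTHER,,N03AA02,90
Pentobarbital calcium,OTHER,,N05CA01,14
Amobarbital,OTHER,,N05CA02,14
Barbital,OTHER,,N05CA04,14
Chloral hydrate,OTHER,,N05CC01,
Bromovalerylurea,OTHER,,N05CM03,
Triclofos sodium,OTHER,,N05CM07,
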