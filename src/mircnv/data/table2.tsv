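mirna_id	mirna_position	dupl	minimal_region	n_records
mir-1977	chr1:556050-556128	chrM	chr1:554340-569354	6
mir-149	chr2:241044091-241044179		chr2:241039698-241051687	6
mir-566	chr3:50185763-50185856		chr3:50173490-50214015	7
mir-1324	chr3:75762604-75762699		chr3:75761737-75839337	6
mir-570	chr3:196911452-196911548		chr3:196905807-196918722	9
mir-548i-2	chr4:9166887-9167035		chr4:9152768-9182838	9
mir-548i-3	chr8:7983873-7984021		chr8:7965981-8024983	14
mir-383	chr8:14755318-14755390		chr8:14741501-14763659	8
mir-661	chr8:145091347-145091435		chr8:145090343-145104971	8
mir-1299	chr9:68292059-68292141		chr9:68291272-68298205	7
mir-126	chr9:138684875-138684959		chr9:138680837-138688363	14
mir-202	chr10:134911006-134911115		chr10:134903011-134918923	10
mir-1268	chr15:20014593-20014644		chr15:19975453-20046356	37
mir-1233	chr15:32461562-32461643	chr15	chr15:32461525-32469857	9
mir-1233	chr15:32607783-32607864	chr15	chr15:32599966-32615283	17
mir-662	chr16:760184-760278		chr16:750040-764098	6
mir-1972	chr16:68621750-68621826	chr11	chr16:68621490-68653097	6
mir-142	chr17:53763592-53763678		chr17:53751608-53767652	11
mir-1270	chr19:20371080-20371162		chr19:20370872-20383238	9
mir-663	chr20:26136822-26136914		chr20:26136626-26139184	6
mir-650	chr22:21495270-21495365		chr22:21494381-21502189	38
mir-514-2	chrX:146171153-146171240		chrX:146168796-146174575	6
mir-514-3	chrX:146173851-146173938		chrX:146168796-146174575	6
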