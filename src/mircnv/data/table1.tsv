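set_label	mirna_id	mirna_position	dupl	cnv_region	genotypes	cnv_id
polymorphic-SMC	mir-1268	chr15:20014593-20014644		chr15:19803370-20089386	2,3,4,5,6	2057
polymorphic-SMC	mir-1233	chr15:32607783-32607864	chr15	chr15:32487975-32617680	0,1,2,3	2082
polymorphic-SMC	mir-1972	chr16:15011679-15011755	chr16	chr16:14897364-15016088	2,3,4	2141
polymorphic-SMC	mir-384	chrX:76056092-76056179		chrX:76053855-76057477	0,1,2	2648
polymorphic-DC	mir-1977	chr1:556050-556128	chrM	chr1:554403-560267	2,3,4	3.1
polymorphic-DC	mir-1324	chr3:75762604-75762699		chr3:75464498-75782745	1,2	1432.2
polymorphic-DC	mir-548i-2	chr4:9166887-9167035		chr4:9117494-9354801	1,2	1815.3
polymorphic-DC	mir-1275	chr6:34075727-34075806		chr6:34071086-34077139	1,2	2853.1
polymorphic-DC	mir-1302-2	chr9:20144-20281	chr1,chr15,chr19	chr9:485-38531	2,3	4134_full
polymorphic-DC	mir-1233	chr15:32461562-32461643	chr15	chr15:32450046-32662643	2,3,4,5	6351.3
polymorphic-DC	mir-1233	chr15:32607783-32607864	chr15	chr15:32450046-32662643	2,3,4,5	6351.3
polymorphic-DC	mir-650	chr22:21495270-21495365		chr22:20711019-21578950	0,1,2	8103_full
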