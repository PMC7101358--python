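contrast	lnc_id	precursor_name
Gt6-Gc	lncRNA_PveLR15531	mir396a
Gt6-Gc	lncRNA_PveLR12931	mir166g
Gt6-Gc	lncRNA_PveLR14505	mir166a
Gt6-Gc	lncRNA_PveLR6504	mir393b
Gt6-Gc	lncRNA_PveLR6753	mir169o
Gt6-Gc	lncRNA_PveLR5421	mir477
Gt6-Gc	lncRNA_PveLR13015	mir319a
Gt6-Gc	lncRNA_PveLR17263	mir156g
Gt24-Gc	lncRNA_PveLR15531	mir396a
Gt24-Gc	lncRNA_PveLR14254	mir396d
Gt24-Gc	lncRNA_PveLR14505	mir166a
Gt24-Gc	lncRNA_PveLR10955	mir164a
Gt24-Gc	lncRNA_PveLR6753	mir169o
Gt24-Gc	lncRNA_PveLR8715	mir167c
Gt24-Gc	lncRNA_PveLR13015	mir319a
Gt24-Gc	lncRNA_PveLR17263	mir156g
Gt24-Gc	lncRNA_PveLR3941	mir156b
Gt24-Gc	lncRNA_PveLR5421	mir477
St6-Sc	lncRNA_PveLR12931	mir166g
St6-Sc	lncRNA_PveLR14505	mir166a
St6-Sc	lncRNA_PveLR3337	mir160i
St6-Sc	lncRNA_PveLR6753	mir169o
St6-Sc	lncRNA_PveLR13016	mir319a
St6-Sc	lncRNA_PveLR17262	mir156g
St6-Sc	lncRNA_PveLR3941	mir156b
St6-Sc	lncRNA_PveLR8830	mir397a
St6-Sc	lncRNA_PveLR15531	mir396a
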