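abbreviation	full_name	occurrence
ac4C	N4-acetylcytidine	tRNA
acp3U	3-(3-amino-3-carboxypropyl)uridine	tRNA
Am	2'-O-methyladenosine	rRNA, snRNA, snoRNA
Cm	2'-O-methylcytidine	rRNA, snRNA, tRNA
cm5U	5-carboxymethyluridine	tRNA
D	Dihydrouridine	rRNA, tRNA
f5C	5-formylcytidine	tRNA
f5Cm	5-formyl-2'-O-methylcytidine	tRNA
Gm	2'-O-methylguanosine	rRNA, snRNA, tRNA
hm5C	5-hydroxymethylcytidine	tRNA
hm5Cm	2'-O-methyl-5-hydroxymethylcytidine	tRNA
I	Inosine	tRNA
i6A	N6-isopentenyladenosine	tRNA
m1A	1-methyladenosine	rRNA, tRNA
m1G	1-methylguanosine	rRNA, tRNA
m1I	1-methylinosine	tRNA
m1Y	1-methylpseudouridine	unknown
m227G	N2,N2,7-trimethylguanosine	rRNA
m22G	N2,N2-dimethylguanosine	tRNA, rRNA
m2G	N2-methylguanosine	rRNA, snRNA, tRNA
m3C	3-methylcytidine	tRNA
m3U	3-methyluridine	rRNA
m5C	5-methylcytidine	tRNA, rRNA
m5U	5-methyluridine	tRNA, rRNA
m5Um	5,2'-O-dimethyluridine	tRNA
m66A	N6,N6-dimethyladenosine	rRNA
m6A	N6-methyladenosine	rRNA, snRNA
m6Am	N6,2'-O-dimethyladenosine	snRNA
m6t6A	N6-methyl-N6-threonylcarbamoyladenosine	tRNA
m7G	7-methylguanosine	rRNA, tRNA, miRNA
manQ	Mannosyl-queuosine	tRNA
galQ	Galactosyl-queuosine	tRNA
mchm5U_R	5-(carboxyhydroxymethyl)uridine methyl ester (R)	tRNA
mchm5U_S	5-(carboxyhydroxymethyl)uridine methyl ester (S)	tRNA
mcm5s2U	5-methoxycarbonylmethyl-2-thiouridine	tRNA
mcm5U	5-methoxycarbonylmethyluridine	tRNA
mcm5Um	5-methoxycarbonylmethyl-2'-O-methyluridine	tRNA
ms2i6A	2-methylthio-N6-isopentenyladenosine	tRNA
ms2t6A	2-methylthio-N6-threonylcarbamoyladenosine	tRNA
ncm5U	5-carbamoylmethyluridine	tRNA
ncm5Um	5-carbamoylmethyl-2'-O-methyluridine	tRNA
oHyW	Hydroxywybutosine	tRNA
Q	Queuosine	tRNA
t6A	N6-threonylcarbamoyladenosine	tRNA
Um	2'-O-methyluridine	rRNA, snRNA, snoRNA, tRNA
Y	Pseudouridine	rRNA, snRNA, snoRNA, tRNA
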