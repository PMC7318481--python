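species	gene_id	leader	core	recognition	product	accession	source
Amanita exitialis	Ae1	MSDINATRLP	FIWVFGIP	GDIGTVLTRGENLC		MN318165	cloned
Amanita exitialis	Ae2	MSDINATRLP	IIWIIGNP	CVSDDVERILTRGESLC		MN318166	cloned
Amanita exitialis	Ae3	MSDINATRLP	IWGIGCDP	CVGDDVTALLTRGEALC	beta-amanitin	MN264225	cloned
Amanita exitialis	Ae4	MSDINATRLP	IWGIGCNP	CVGDDVTSVLTRGEALC	alpha-amanitin	MN264220	cloned
Amanita exitialis	Ae5	MSDINATRLP	AWLTDCP	CVGDDVNRLLTRGESLC	phallotoxin-like	MN264235	cloned
Amanita exitialis	Ae6	MSDINATRLP	AWLVDCP	CVGDDVNRLLTRGESLC	phallacidin	MN264231	cloned
Amanita exitialis	Ae7	MSDINATRLP	VWIGYSP	CVGDDCIALLTRGEGLC		MN318167	cloned
Amanita exitialis	Ae8	MSDINATRLP	GFLFWA	YVGDDVDYILTRGESLA		MN318168	cloned
Amanita exitialis	Ae9	MSDINATRLP	GFLLWA	YVGDDVDYILTRGESLA		MN318169	cloned
Amanita fuliginea	Af1	MSDINATRLP	FPHFPPYNPP	CVSDDIHMVLTRGENLC		MN318170	cloned
Amanita fuliginea	Af2	MSDINATRLP	YYLLLILPP	CVSDDLQTVLTRGENLC		MN318171	cloned
Amanita fuliginea	Af3	MSDINATRLP	IFWFIYFP	CVGDDVDNTLARGESLS		MN318172	cloned
Amanita fuliginea	Af4	MSDINATRLP	IWGIGCDP	CVGDDVAALITRGEALC	beta-amanitin	MN264226	cloned
Amanita fuliginea	Af5	MSDINATRLP	IWGIGCDP	CVGEDVAALITRGEALC	beta-amanitin	MN318173	cloned
Amanita fuliginea	Af6	MSDINATRLP	IWGIGCNP	SVGDEVTALLTSGEALC	alpha-amanitin	MN318174	cloned
Amanita fuliginea	Af7	MSDINATRLP	LPSRPVFP	FVSDAIEVVLGRGEDLC		MN318175	cloned
Amanita fuliginea	Af8	MSDINASRLP	AWLATCP	CIGDDVNPTITRGESLC	phalloidin	MN264249	cloned
Amanita fuliginea	Af9	MSDINATRLP	AWLVDCP	CVGDDVNRLLARGENLC	phallacidin	MN264232	cloned
Amanita molliuscula	Am1	MSDINATRLA	IWGIGCDP	CVGDDVTALLTRGEALC	beta-amanitin	MN264227	cloned
Amanita pallidorosea	Ap1	MSDINATRLP	LIFIPPFIPP	CVSDDIQMVLTRGENLC		MN318176	cloned
Amanita pallidorosea	Ap2	MSDINAPRLP	LIFIPPFIPP	CVSDDIQMVLTRGEGLC		MN318177	cloned
Amanita pallidorosea	Ap3	MSDINATRLP	IPFHIPAP	SVGDDIEVVLGRGENLC		MN318178	cloned
Amanita pallidorosea	Ap4	MSDINATRLP	IWGIGCDP	CVGDDVTAVLTCGEALC	beta-amanitin	MN318179	cloned
Amanita pallidorosea	Ap5	MSDINATRLP	IWGIGCDP	CVGDDVTAVLTRGEALC	beta-amanitin	MN264228	cloned
Amanita pallidorosea	Ap6	MSDINATRLP	IWGIGCNP	CVGDEVAALLTRGEALC	alpha-amanitin	MN264222	cloned
Amanita pallidorosea	Ap7	MSDINATRLP	IWGIGCNP	CVGDEVTALITRGEALC	alpha-amanitin	MN264221	cloned
Amanita pallidorosea	Ap8	MSDINATRLP	AWLATCP	CAGDDVNPTLTRGESLC	phalloidin	MN318180	cloned
Amanita pallidorosea	Ap9	MSDINATRLP	AWLMTCP	CVGDDVNPILTRGESVC	phallotoxin-like	MN318181	cloned
Amanita pallidorosea	Ap10	MSDINATRLP	AWLMTCP	CVGDDVNPTLTRGESLC	phallotoxin-like	MN264236	cloned
Amanita pallidorosea	Ap11	MSDVNATRLP	AWLVDCP	CVGDDINRLLTRGENLC	phallacidin	MN264233	cloned
Amanita rimosa	Ar1	MSDINATRLP	IWGIGCDP	CVGDDVAALATRGEALC	beta-amanitin	MN318182	cloned
Amanita rimosa	Ar2	MSDINATRLP	IWGIGCDP	CVGDDVAALTTRGEALC	beta-amanitin	MN264229	cloned
Amanita rimosa	Ar3	MSDINATRLP	IWGIGCNP	SVGDEVTALLASGEALC	alpha-amanitin	MN318183	cloned
Amanita rimosa	Ar4	MSDINSTRLP	IWGIGCNP	SVGDEVTALLTRGEALC	alpha-amanitin	MN264223	cloned
Amanita rimosa	Ar5	MSDINATRVP	AWLAECP	CVGDDISHLLTRGENLC	phallotoxin-like	MN264237	cloned
Amanita subfuliginea	Asf1	MSDINATRLP	HPFPLGLQP	CAGDVDNFTLTKGEGLC		MN318184	cloned
Amanita subfuliginea	Asf2	MSDINATRLP	AIFLAWPP	CVGDNVNSTLTRGESLC		MN318185	cloned
Amanita subfuliginea	Asf3	MSDINATRLP	IWGIGCDP	CVSDDVAALLTRGEALC	beta-amanitin	MN318186	cloned
Amanita subfuliginea	Asf4	MSDINATRLP	IWGIGCNP	CVGDEVAALLTRGEALC	alpha-amanitin	MN318187	cloned
Amanita subfuliginea	Asf5	MSDINATRLP	AWLVDCP	CVGDDVNRLITRGENLC	phallacidin	MN318188	cloned
Amanita subjunquillea	Asj1	MSDINATRLP	AYLPLFFIPP	CVSDDIEMVLTRGESLC		MN318189	cloned
Amanita subjunquillea	Asj2	MSDINATRLP	AYLPLFFIPP	CVSDDIEVVLTRGESLC		MN318190	cloned
Amanita subjunquillea	Asj3	MSDINATRLP	IWGIGCDP	CIGDDVTALLTRGEALC	beta-amanitin	MH142177	cloned
Amanita subjunquillea	Asj4	MSDINATRLP	IWGIGCDP	CVGDEVTALLTRGEALC	beta-amanitin	MH142176	cloned
Amanita subjunquillea	Asj5	MSDINATRLP	IWGIGCNP	CVGDEVAALLTRGEALC	alpha-amanitin	MH142175	cloned
Amanita subjunquillea	Asj6	MSDINATRLP	AWLATCP	CAGDDVNPTLTRGESLC	phalloidin	MN264250	cloned
Amanita subjunquillea	Asj7	MSDINATRLP	AWLATCP	CVGDDVNPTLSRGESLC	phalloidin	MN318191	cloned
Amanita subjunquillea	Asj8	MSDINATRLP	AWLVDCP	CVGDDINRLLTRGENLC	phallacidin	MN264234	cloned
Amanita subpallidorosea	Asp1	MSDINATRLP	IWGIGCDP	CVGDDVAAFLTRGEALC	beta-amanitin	MN264230	cloned
Amanita subpallidorosea	Asp2	MSDINATRLP	IWGIGCNP	SVGDEVTALLTRGEALC	alpha-amanitin	MN264224	cloned
Amanita subpallidorosea	Asp3	MSDINAARLP	AWITDCP	CVGDDINRILTRGENIC	phallotoxin-like	MN272408	cloned
Amanita subpallidorosea	Asp4	MSDINASRFP	AWLATCP	CVGDDVNPTIARGESLC	phalloidin	MN272407	cloned
Amanita subpallidorosea	Asp5	MSDINATRLP	AWLITCP	CVGDDANPTITRGESLC	phallotoxin-like	MN318192	cloned
Amanita subpallidorosea	Asp6	MSDINATRLP	AWLVTCP	CVGDDVNPTITRGESLC	phallotoxin-like	MN272409	cloned
Amanita subpallidorosea	Asp7	MSDINATRLP	AWLVTCP	CVGDDVNSTITRGESLC	phallotoxin-like	MN318193	cloned
Amanita virosa	Av1	MSDINATRLP	FLLFIIPP	CVSDDVNSTLTRGESLC		MN318194	cloned
Amanita virosa	Av2	MSDINATRLP	FYFQPGFP	WSVGDDVNPTLTRGESLC		MN318195	cloned
Amanita virosa	Av3	MSDINATRLP	IWGIGCNP	SVGDEATALLTRGEALC	alpha-amanitin	MN272412	cloned
Amanita virosa	Av4	MSDINATRLP	SILIVWPP	CVGDDVNSTLTRGESLC		MN318196	cloned
Amanita virosa	Av5	MSDINATRLP	SILVVWPP	CVSDDVNSTLTRGESLC		MN318197	cloned
Amanita virosa	Av6	MSDINATRLP	AWLATCP	CVGDDVNPTLARGESLC	phalloidin	MN318198	cloned
Amanita virosa	Av7	MSDINATRLP	AWLVDCP	CVGDDINRLLTRGENLC	phallacidin	MN318199	cloned
Amanita virosa	Av8	MSDINATRLP	AWLVTCP	CVGDDVNPTLTRGESLC	phallotoxin-like	MN318200	cloned
Amanita virosa	Av9	MSDINATRLP	GPFLFFP	FVSDDIEVILRRGEDLC		MN318201	cloned
Galerina marginata	Gm1	MFDTNATRLP	IWGIGCNP	WTAEHVDQTLASGNDIC	alpha-amanitin	MN272413	cloned
Galerina marginata	Gm2	MFDTNSTRLP	IWGIGCNP	WTAEHVDQTLVSGNDIC	alpha-amanitin	MN272414	cloned
Galerina sulciceps	Gs1	MFDTNATRLP	IWGIGCNP	WTAEHVDQTLASGNDIC	alpha-amanitin	MN272417	cloned
Galerina sulciceps	Gs2	MFDTNSTRLP	I*GIGCNP	WTAEHIDQTLVSGNDTC		MN272418	cloned
Lepiota venenata	Lv1	MDANATRLP	IWGIGCNP	WTPESVNDTLTKDLS	alpha-amanitin	MN272421	cloned
Lepiota venenata	Lv2	MDANSTRLP	IWGIGCNP	WAPESVNDTLTRGKDLC	alpha-amanitin	MN272422	cloned
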