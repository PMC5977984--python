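feature_id	S01	S02	S03	S04	S05	S06	S07	S08	S09	S10	S11	S12
GENE01	7.777903632314199	7.369877094644905	8.240350275269874	8.963556603662454	9.08312470209498	8.18655344875169	9.475508117894298	9.580479894799112	9.108192910721577	9.098320232438144	9.31814994890073	10.15606363080257
GENE02	6.692090841824661	6.366042466517869	6.582045037928555	7.81845691878703	7.865576139822267	7.312127554316488	8.296197103206405	7.985864358537625	8.01678693309916	8.179621713132338	8.495603706362537	9.028080605674988
GENE03	3.958754414708836	4.375045687276333	4.145494591702273	4.791099197682645	4.722514177750576	4.396177708530919	5.7417931765889465	5.75948256120038	5.33404618309198	5.628610839209059	6.39150809075585	6.129890744137223
GENE04	9.373839162508274	8.392688542331763	7.923855785201027	9.507808668863465	9.228141881592602	8.780211662737605	8.09666969973493	7.992907531005415	6.872784350731718	7.509349871821475	7.20906739705749	7.370599431291172
GENE05	9.960231294713457	9.368833595270873	9.530103332578658	9.181736089598662	10.02763197398844	9.538429060522386	8.664265331886956	8.436698344013658	7.974862507854081	8.658806258003876	8.113380393639067	7.512879908813233
GENE06	13.104096850988785	12.271764648121883	12.153831884131142	12.417923776594918	12.851076390923938	12.500526596756977	11.276965423786226	10.875082437357918	10.58143478644644	11.351420064674885	11.11275253440379	10.654600035653047
GENE07	7.474461033399182	6.944848802524627	7.157332353626913	7.275640846424285	7.447744100566408	7.868688727844044	7.35534729770432	6.767657947200668	7.5449711398154005	7.2996002511014915	6.827200188928299	6.665517506782681
GENE08	7.312620541839718	7.7454088885402275	7.404415577002256	7.811834057957654	7.547590678550137	7.687029542055792	7.842795228880357	7.805596673950304	7.316176451287528	8.21034749292745	7.038729638646789	7.575527676920396
GENE09	6.914077553575304	7.577605739804538	6.827397744422843	6.910315553191994	6.878851341543867	6.807074934939332	7.0487065223544585	7.274614997757365	6.929668977211174	6.71235045893037	7.136218054382106	7.206838790459497
GENE10	10.957799578007252	10.50140522541541	10.688070769751063	11.016465838460501	10.44651008409185	10.715534083943952	10.636433306325454	10.312119775399232	10.709756285403987	11.081553234801834	11.418054640623804	10.311668071657806
GENE11	10.295735645360544	10.350690574227464	10.381753005535403	9.886332909462551	10.111700496642866	9.833966936901966	10.185511861279121	10.376930650438856	9.943012999867067	10.083785415560321	10.275221445165132	10.232663805310885
GENE12	4.59617168182495	5.2057818590863665	4.940102265128157	4.841060952544546	4.806924761992914	5.004529324758764	5.103838351342835	4.414869766532494	4.535069710715587	4.278257643888215	4.929028371991658	4.911776250396187
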