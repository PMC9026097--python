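# modscape 0.1.0 synthetic fixture
NRF2_UP	synthetic stand-in gene set (fixture; member IDs from the simulator universe); direction=up	G01246	G01851	G02245	G00320	G04092	G04238	G04852	G04789	G02763	G03038	G00952	G03076	G00852	G01943	G02887	G03577	G03135	G03385	G01288	G00194	G02276	G03051	G02665	G02349	G03464	G03967	G02592	G02790	G00949	G03008	G02883	G01711	G01032	G01665	G01223	G03831	G02006	G00253	G01712	G03459	G04264	G04341	G02968	G01093	G01380	G02760	G01505	G02840	G03640	G04487	G01942	G00753	G01977	G00778	G04767	G02713	G03217	G01044	G04372	G01752	G00999	G00327	G04163	G00981	G02106	G01887	G00270	G03258
NRF2_DOWN	synthetic stand-in gene set (fixture; member IDs from the simulator universe); direction=down	G02622	G04628	G01611	G04718	G00096	G00506	G04889	G04322	G02465	G00336	G03113	G02644	G01250	G03918	G02036	G00516	G01516	G03379	G02159	G01652	G04804	G02198	G00734	G04924	G04053	G02334	G03228	G02673	G02570	G01070	G02075	G03818	G00428	G01171	G03262	G04065	G00646	G02129	G01310	G04326	G02604	G04537	G01468	G00454	G00389	G02496	G02091	G02360	G02107	G01549	G04137	G01600	G02048	G01812	G00916	G03980	G02495	G00973	G04707	G04591	G02286	G04624	G01637	G02609	G03211	G02981	G02113	G04084	G00240	G00120	G03052	G04947	G03840	G02338	G04976
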