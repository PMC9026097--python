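# modscape 0.1.0 synthetic fixture
RELA_ACTIVATED	synthetic stand-in gene set (fixture; member IDs from the simulator universe); direction=activated	G01231	G01443	G03950	G04724	G00332	G00595	G03794	G00814	G03664	G02298	G01431	G04756	G01768	G01671	G03760	G00901	G02774	G02796	G01378	G04942	G01014	G01676	G03515	G00471	G01412	G01190	G04741	G04412	G02612	G00281	G04722	G03090	G00964	G01135	G04694	G03631	G00823	G02744	G02158	G00553	G03159	G02629	G01862	G00530	G03825	G03092	G03117	G04039	G04258	G00705	G01840	G02205	G04977	G01815	G04958	G04504	G04961	G02320	G03422	G01491	G01763	G04417	G01881	G02711	G02252	G04713	G04292	G04706	G04244	G02702	G00128	G02361	G04821	G01885	G04965	G04847	G02385	G03171	G01265	G00931	G02623	G02771	G04267	G04690	G01769	G00927	G04099	G03185	G02587	G04432	G00615	G01634	G01612	G02167	G01379	G04387	G01575	G01027	G01968	G02131	G04482	G00757	G02715	G00032	G02435	G01272	G01196	G02519	G02599	G01035	G00456	G00505	G04327	G02484	G02030	G00477	G02308	G03332	G04916	G04937	G04152	G02430	G04998	G02888	G00619	G00298	G00316	G03081	G04467	G01955	G00869	G00896	G00503	G02666	G02180	G02635	G04783	G00137	G01339	G01088	G01721	G00802	G04569	G00119	G03450	G02397	G00387	G02061	G03504	G03772	G00515	G01471	G03750	G04377	G02977	G03580	G01557	G02059	G00771	G02518	G01878	G02473	G02090	G04911	G01192	G01066	G00722	G04419	G00954	G01629	G01920	G00587	G01856	G03241	G00774	G01362	G02074	G02020	G03343	G01344	G00654	G04159	G00580	G02643	G00923	G02340	G00751	G01225	G02112	G00730	G02407	G00502	G01698	G04421	G00572	G03920	G00113	G02539	G04738	G00982	G04827	G01028	G02597	G01292	G02060	G02135	G04840	G00521	G01031	G00920	G03420	G02111	G04223	G04128	G03240	G04191	G01220	G04385	G02150	G03761	G03299	G03694	G02699	G02346	G03436	G03665	G00033	G03040	G00127	G00755	G04554	G02199	G01062	G03204	G03098	G04436	G03394	G00504	G02564	G04910	G01872	G03938	G01449	G00588	G00381	G02467	G01524	G02062	G00249	G02653	G00140	G03296	G04945	G01348	G03735	G03800	G02026	G04358	G03110	G04462	G02088	G01336	G00528	G00124	G04283	G02141	G04834	G01195	G01982	G01113	G04122	G02722	G02288	G01993	G03522	G01683	G01373	G01307	G02115	G02710	G01469	G01552	G00933	G03246	G03261	G04222	G01299	G03812	G03715	G01473	G02283	G04656	G04759	G03358	G01664	G02667	G04646	G01907	G04743	G04793	G04121	G01018	G04063	G00732
RELA_SUPPRESSED	synthetic stand-in gene set (fixture; member IDs from the simulator universe); direction=suppressed	G04817	G04306	G02132	G01071	G02029	G04661	G00116	G00816	G01688	G01642	G00322	G02967	G01155	G01349	G02575	G03846	G02015	G04437	G02227	G00439	G02531	G01961	G00970	G00337	G01126	G04495	G02452	G01281	G03703	G02318	G01011	G01446	G03882	G02748	G04919	G00675	G03549	G00427	G04799	G00181	G02784	G02584	G02324	G02561	G03119	G00864	G01148	G04553	G02041	G04014	G00535	G04725	G01421	G03094	G01829	G00905	G04863	G00117	G02930	G00416	G01700	G03570	G03212	G00746	G01416	G02655	G03430	G04347	G04526	G02758	G03525	G04489	G03293	G00891	G01375	G02681	G02033	G03600	G01397	G02451	G03699	G02023	G01901	G01650	G01845
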