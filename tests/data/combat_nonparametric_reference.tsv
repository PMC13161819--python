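# Reference harmonized values computed with Bioconductor sva::ComBat
# (par.prior=FALSE) on the deterministic fixture built in
# tests/test_harmonize.py (seed 42). Regenerate with sva if the
# fixture changes.
X0	X1	X2	X3	X4	X5	X6	X7	X8	X9	X10	X11
1.8746163294	-0.207427180326	2.28714133203	1.62556221591	-0.213072669376	-0.450087893151	1.20781980472	-0.369453425689	1.04379044095	-0.978207791149	2.06011640429	0.87122585552
1.48254726192	1.5699860645	1.85005591161	-0.248462603244	1.75965353321	-0.339626199621	2.45006829299	0.257219608384	1.23217087618	-0.46551954496	2.84418340081	0.137408735043
1.10687086045	0.397666666526	2.08713796193	1.1299075889	1.96511790585	1.19662046966	4.17867068449	0.215831812189	1.18991499413	-0.242925908734	2.46049514497	1.94495283322
1.21548518798	-0.24195178507	0.568092319707	1.11632349953	1.99651242972	1.01843239931	0.71311645446	0.73260961307	1.60567491534	0.717235968462	2.4669074441	0.72283526106
2.08416839072	0.772099612499	1.72240356657	1.2952735398	0.101699602584	0.412695741528	0.908802143494	-0.194025842678	1.13031737017	2.2270798221	0.460101176109	1.62950965684
-4.9246776944e-05	0.445051566592	1.70799233192	1.29749532721	2.21558009539	1.48918018324	1.61380561528	0.470708449404	2.98565208239	0.778850669741	0.559983196599	-0.292049203805
0.485272730701	0.972936550678	1.45940647893	1.15028651279	0.936801314868	0.662296167593	2.36327964218	0.269973082597	2.17094699827	-0.131723837798	1.23690826236	0.187496953913
0.371469309544	1.21248135977	1.07748270972	0.751343035484	2.00091811229	1.173177069	2.52929125923	0.695795011768	1.31161004619	0.716786014336	-0.102201359895	-0.812630408215
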