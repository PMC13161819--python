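# Reference harmonized values computed with Bioconductor sva::ComBat
# (par.prior=TRUE) on the deterministic fixture built in
# tests/test_harmonize.py (seed 42). Regenerate with sva if the
# fixture changes.
X0	X1	X2	X3	X4	X5	X6	X7	X8	X9	X10	X11
1.8479984607	-0.238090222514	2.26266744046	1.60442559595	-0.250540686426	-0.482012092884	1.22520018264	-0.366481910685	1.0525313076	-1.00729968286	2.12238768414	0.9395445888
1.45923090946	1.65269755532	1.8474665542	-0.2683091789	1.75196560287	-0.364614279871	2.45663789282	0.257149087449	1.21853899518	-0.477578268638	2.85729025795	0.135350889866
1.08462732976	0.444231096569	2.15739886836	1.24557107803	2.02386419897	1.31857942405	4.07876937	0.215753122719	1.20819469662	-0.224864455743	2.4285337204	1.87650144891
1.2225346674	-0.27355232392	0.53965650131	1.15917358464	2.04637205678	1.05591681696	0.682361945799	0.717196910628	1.59266264	0.701517669466	2.47101470674	0.707228264528
2.17851001405	0.751403257421	1.78426228656	1.32155302917	0.0180351354683	0.359728473362	0.915413487338	-0.187714278029	1.13699066266	2.23406846986	0.466587036852	1.63633118895
-0.130465246978	0.411158508602	1.70665137815	1.32802061791	2.25259705688	1.5341909127	1.63209136821	0.487156845526	3.01204474978	0.797120029566	0.572041395338	-0.280108317233
0.411991532793	1.02085633756	1.46859722787	1.2132210722	0.901747353682	0.683916570834	2.36535546261	0.266578371447	2.17210740261	-0.137030443994	1.23362306619	0.183709693819
0.242740331825	1.2389489303	1.02458420607	0.728281322667	2.04720263309	1.19542310067	2.52981816457	0.722950923753	1.33850861833	0.743487318235	-0.0446834738374	-0.752806099822
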