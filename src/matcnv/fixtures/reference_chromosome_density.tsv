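# Distinct maternal CNVs (>= 200 kb) per chromosome in the reference screening
# cohort, with effective chromosome lengths (bp of mappable, non-repetitive
# sequence; centromeres and acrocentric p-arms removed).
chrom	effective_length_bp	n_variants
1	231223641	64
2	240863511	71
3	198255541	67
4	189962376	58
5	181358067	55
6	170078524	60
7	158970135	60
8	144768136	54
9	122084564	41
10	133263006	45
11	134634058	37
12	133137821	34
13	97983128	29
14	91660769	31
15	85089576	26
16	83378703	32
17	83481871	24
18	80089650	24
19	58440758	8
20	63944268	15
21	40088623	9
22	40181019	14
X	154893034	84
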