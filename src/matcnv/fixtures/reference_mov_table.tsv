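# Most frequent recurrent maternal CNVs (MOVs) of the reference screening cohort, N = 6,422.
# coordinates: GRCh37, 0-based half-open, 20 kb bin-aligned, printed report style.
# dbvar_dgv_nf_pct / gnomad_nf_pct: non-Finnish European population frequencies (%).
cnv	size	coordinates	n	frequency_pct	dbvar_dgv_nf_pct	gnomad_nf_pct
dup 6q27	240 kb	chr6:168,340,000–168,580,000	126	1.962	3.1	1.4
dup 22q11.22	260 kb	chr22:22,300,000–22,560,000	98	1.526	0.7	0
dup 8p23.2	200 kb	chr8:2,360,000–2,560,000	58	0.903	1	0.48
dup 11q25	360 kb	chr11:134,360,000–134,720,000	55	0.856	0.9	0.39
dup 15q13.3	480 kb	chr15:32,020,000–32,500,000	42	0.654	0.8	0.23
dup 15q11.2	320 kb	chr15:22,760,000–23,080,000	38	0.592	0.3	0
dup Xp22.31	1.66 Mb	chrX:6,220,000–8,960,000	31	0.483	0.1	0
dup 1q25.1	320 kb	chr1:175,420,000–175,740,000	30	0.467	0.1	0.06
del 17q22	340 kb	chr17:50,960,000–51,300,000	28	0.436	0	0.026
del 9p23	260 kb	chr9:11,920,000–12,180,000	27	0.420	1.2	0.01
dup 12p11.1	500 kb	chr12:34,300,000–34,800,000	24	0.374	0.1	0.026
dup 12q24.13-q24.21	280 kb	chr12:114,260,000–114,540,000	20	0.311	0	0
dup 19q13.41	320 kb	chr19:52,280,000–52,600,000	20	0.311	0.4	0.026
dup 6p11.2	600 kb	chr6:57,400,000–58,000,000	20	0.311	0.1	0.026
dup 7q11.21	200 kb	chr7:64,680,000–64,880,000	19	0.296	0.4	0.26
dup 2p22.3	680 kb	chr2:32,640,000–33,320,000	18	0.28	0.1	0.18
dup 14q21.2	440 kb	chr14:43,820,000–44,260,000	17	0.265	0.4	0.15
del 7q11.21	220 kb	chr7:64,680,000–64,880,000	17	0.265	0.4	0.26
dup 3p26.3	360 kb	chr3:2,660,000–3,020,000	16	0.249	0	0
dup 7q11.21b	480 kb	chr7:62,040,000–62,640,000	16	0.249	0	0.31
dup Xq27.2	380 kb	chrX:140,360,000–140,740,000	14	0.218	0.3	0.44
del 15q11.2	240 kb	chr15:22,840,000–23,080,000	13	0.202	0.1	0.18
del 2p22.3	260 kb	chr2:35,760,000–36,080,000	12	0.187	0.2	0.066
del 4q35.2	1.6 Mb	chr4:188,280,000–189,920,000	12	0.187	0	0.026
dup 4q35.2	480 kb	chr4:188,700,000–189,180,000	12	0.187	0	0
del 6q26	800 kb	chr6:162,340,000–163,140,000	12	0.187	0	0
del 7q31.1	460 kb	chr7:110,840,000–111,300,000	12	0.187	0.2	0
dup Xp21.1	240 kb	chrX:33,000,000–33,920,000	12	0.187	0	0.017
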