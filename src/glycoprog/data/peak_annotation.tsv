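# Synthetic 24-peak IgG N-glycome annotation (glycoprog packaged convention).
# One row per chromatographic peak GP1..GP24 of a HILIC-UPLC IgG glycome run.
# Columns: structure = biantennary glycoform shorthand (F core fucose, A2 biantennary,
# B bisecting GlcNAc, G galactoses, S sialic acids, M5 oligomannose);
# galactose / sialic = residue counts; fucose / bisecting = 0/1 flags;
# reference_pct = reference composition (percent of total chromatogram area, used as
# the technical-standard profile and the generator's mean profile; calibrated so the
# derived-trait means of an average cohort sit near published IgG values,
# e.g. G0n ~ 38, G1n ~ 44, G2n ~ 17.5, Fn ~ 80, FBn ~ 16).
# This mapping is a coherent synthetic stand-in for the laboratory convention, which
# is configurable: pass an alternative table to PeakAnnotation.from_tsv().
peak	structure	galactose	sialic	fucose	bisecting	reference_pct
GP1	FA1	0	0	1	0	0.2
GP2	A2	0	0	0	0	0.4
GP3	A2B	0	0	0	1	0.1
GP4	FA2	0	0	1	0	23.9
GP5	M5	0	0	0	0	0.1
GP6	FA2B	0	0	1	1	5.8
GP7	A2G1	1	0	0	0	0.9
GP8	FA2[6]G1	1	0	1	0	18.7
GP9	FA2[3]G1	1	0	1	0	9.8
GP10	FA2BG1	1	0	1	1	5.5
GP11	FA2G1S1	1	1	1	0	4.0
GP12	A2G2	2	0	0	0	0.6
GP13	A2BG2	2	0	0	1	0.3
GP14	FA2G2	2	0	1	0	11.6
GP15	FA2BG2	2	0	1	1	1.5
GP16	FA2BG1S1	1	1	1	1	0.6
GP17	A2G1S1	1	1	0	0	0.3
GP18	FA2G2S1	2	1	1	0	8.5
GP19	FA2BG2S1	2	1	1	1	1.4
GP20	A2G2S1	2	1	0	0	0.4
GP21	A2G2S2	2	2	0	0	0.3
GP22	FA2G2S2	2	2	1	0	1.2
GP23	FA2BG2S2	2	2	1	1	1.5
GP24	A2BG2S2	2	2	0	1	0.2
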