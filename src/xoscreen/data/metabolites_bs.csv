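# Metabolites annotated in the ethyl acetate extract of Balanophora subcupularis
# (negative-mode LC-QToF-HRMS). measured_mz is the printed precursor ion m/z (3 decimals);
# ppm_printed is the published mass error recomputed from full-precision measurements,
# so re-deriving it from the 3-decimal measured_mz will not reproduce nonzero entries.
# Note: the ellagic acid row prints 300.998 with 0.00 ppm although the theoretical
# [M-H]- m/z rounds to 300.999; treat that row as display-rounding inconsistent.
# Note: row 10 prints adduct [M+Cl]- with m/z 477.103 and 0.00 ppm, but 477.103 is the
# [M-H]- value of C22H22O12 ([M+Cl]- would be ~513.08); the published adduct label and
# m/z are mutually inconsistent. Transcribed verbatim; exclude from m/z round-trips.
no,rt_min,name,adduct,measured_mz,formula,ppm_printed
1,1.13,D-saccharose,[M-H]-,341.109,C12H22O11,2.93
2,1.17,D-trehalose,[M+HCOO]-,387.115,C12H22O11,2.58
3,1.35,malic acid,[2M+Na-2H]-,289.018,C4H6O5,3.46
4,4.09,gallic acid,[M-H]-,169.014,C7H6O5,0.00
5,5.61,"1,6-di-O-gallyol-beta-D-glucose",[M-H]-,483.076,C20H20O14,-2.07
6,6.25,strictinin,[M-H]-,633.073,C27H22O18,0.00
7,6.28,1-O-vanilloyl-beta-D-glucose,[M-H]-,329.088,C14H18O9,3.04
8,7.57,"1,3,6-tri-O-galloyl-beta-D-glucose",[M-H]-,635.086,C27H24O18,-3.15
9,8.21,"1,2,4,6-tetra-O-galloyl-beta-D-glucopyranoside",[M-H]-,787.099,C34H28O22,0.00
10,8.34,"6-O-[(2E)-3-(4-hydroxyphenyl)-2-propenoyl]-1-O-(3,4,5-trihydroxybenzoyl)hexopyranose",[M+Cl]-,477.103,C22H22O12,0.00
11,8.37,pyracanthoside,[M-H]-,449.109,C21H22O11,2.23
12,8.47,lariciresinol-4-O-beta-D-glucoside,[M-H]-,521.202,C26H34O11,0.00
13,8.89,pentagalloyl glucose,[M-H]-,939.108,C41H32O26,-2.13
14,9.19,"1,6-di-O-galloyl-2-O-p-coumaroyl-beta-D-glucose",[M-H]-,629.112,C29H26O16,-3.18
15,9.26,luteolin-7-O-glucoside,[M-H]-,447.092,C21H20O11,-2.24
16,9.41,"(6R,7R,8S)-isolariciresinol",[M-H]-,359.15,C20H24O6,2.78
17,9.56,ellagic acid,[M-H]-,300.998,C14H6O8,0.00
18,9.67,rosmarinic acid,[M-H]-,359.077,C18H16O8,0.00
19,9.72,azelaic acid,[M-H]-,187.098,C9H16O4,5.34
20,9.98,phloretin,[M-H]-,273.076,C15H14O5,0.00
21,9.98,naringenin,[M-H]-,271.061,C15H12O5,0.00
22,9.98,phloridizin,[M-H]-,435.128,C21H24O10,-2.30
23,10.10,1-O-(E)-cinnamoyl-4-galloyl-beta-D-glucopyranose,[M-H]-,461.109,C22H22O11,2.17
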