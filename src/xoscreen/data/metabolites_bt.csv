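# Metabolites annotated in the ethyl acetate extract of Balanophora tobiracola
# (negative-mode LC-QToF-HRMS). Same column conventions as metabolites_bs.csv.
no,rt_min,name,adduct,measured_mz,formula,ppm_printed
1,4.49,strictinin,[M-H]-,633.073,C27H22O18,0.00
2,5.96,"1,6-di-O-gallyol-beta-D-glucose",[M-H]-,483.077,C20H20O14,0.00
3,7.00,"1-(3,4-dihydroxyphenyl)-6,7-dihydroxy-1,2-dihydro-2,3-naphthalenedicarboxylic acid",[M-H]-,357.062,C18H14O8,2.80
4,7.08,7-beta-1-D-glucopyranosyl 11-methyl oleoside,[M-H]-,565.176,C23H34O16,-1.77
5,7.36,"1,3,6-tri-O-galloyl-beta-D-glucose",[M-H]-,635.088,C27H24O18,0.00
6,7.49,secoxyloganin,[M-H]-,403.125,C17H24O11,2.48
7,7.93,taxifolin,[M-H]-,303.051,C15H12O7,3.30
8,8.33,lariciresinol-4-O-beta-D-glucoside,[M-H]-,521.202,C26H34O11,0.00
9,8.35,"1,2,4,6-tetra-O-galloyl-beta-D-glucopyranoside",[M-H]-,787.098,C34H28O22,-1.27
10,8.38,pyracanthoside,[M+Cl]-,485.085,C21H22O11,0.00
11,8.56,luteolin-7-O-glucoside,[M-H]-,447.093,C21H20O11,0.00
12,8.60,quercetin 7-O-beta-D-glucopyranoside,[M-H]-,463.088,C21H20O12,0.00
13,8.90,secoisolariciresinol,[M-H]-,361.166,C20H26O6,-2.77
14,8.96,prunin,[M-H]-,433.114,C21H22O10,2.31
15,9.00,1-O-caffeoyl-6-O-(S)-brevifolincarboxyl-beta-D-glucopyranose,[M-H]-,615.097,C28H24O16,-3.25
16,9.10,1-O-(E)-cinnamoyl-4-galloyl-beta-D-glucopyranose,[M-H]-,461.108,C22H22O11,0.00
17,9.13,ellagic acid,[M-H]-,300.999,C14H6O8,3.32
18,9.68,oleuropein,[M-H]-,539.175,C25H32O13,-1.85
19,9.83,phloridizin,[M-H]-,435.129,C21H24O10,0.00
20,10.32,naringenin,[M-H]-,271.061,C15H12O5,0.00
21,14.81,gingerglycolipid A,[M+HCOO]-,721.364,C33H56O14,-1.39
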