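# Coarse-grained Nf side-arm (C-terminal tail) bead tables: one bead per
# residue, uniform integer charge per block. Net charges (dephosphorylated):
# NfL -25, NfM -43, NfH -44. phospho_sites = number of KSP serines in the
# block, evenly spaced; phosphorylation adds -2e at each site. All values are
# editable model inputs, not measured quantities.
# species	block_start	block_end	charge_per_bead	phospho_sites
NfL	0	45	0	0
NfL	46	70	-1	0
NfL	71	142	0	0
NfM	0	101	0	0
NfM	102	144	-1	0
NfM	145	509	0	13
NfH	0	97	0	0
NfH	98	141	-1	0
NfH	142	605	0	44
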