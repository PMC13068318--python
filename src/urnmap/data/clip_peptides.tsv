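# CLIP (class II-associated invariant chain peptide) fragments bound in the
# DR and DQ prototype grooves; URN numbering starts at 1 at the first residue.
group	sequence	core_start	core_end
dr	PVSKMRMATPLLMQALPM	3	14
dq	PVSKMRMATPLLMQA	4	14
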