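chrom	start	end	label
6	28909037	30913661	HLA
9	135130951	137150617	ABO
19	44409011	46412650	APOE
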