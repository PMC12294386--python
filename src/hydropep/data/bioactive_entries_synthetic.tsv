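entry_id	sequence	activity	source_db	parent_accession
BP0567	SSLLEKGLDGAKKAVGGLGKLGKDAVEDLESVGKGAVHDVKDVLDSV	antimicrobial	StraPep	P81605
satpdb12186	TITLEVEPSDTIENVKAKIQDKEGIPPDQQRLIFAGK	antimicrobial	APD2	P0CG47
MIF-FRAG-1	TNVPRASVPDGFLS	cytokine/growth factor	StraPep	P14174
MIF-FRAG-2	TNVPRASVPDGFLSEL	cytokine/growth factor	StraPep	P14174
MIF-FRAG-3	VHVVPDQLMAF	cytokine/growth factor	StraPep	P14174
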