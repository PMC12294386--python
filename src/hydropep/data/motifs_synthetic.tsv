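# snapshot_id: hydropep-motifs-synthetic-v1
# Synthetic pinned snapshot of ACE-inhibitor and DPP-IV-inhibitor fragment
# motifs in the style of the BIOPEP-UWM bioactive-fragment tables.  The live
# database changes between access dates; this fixed excerpt makes frequency-
# of-bioactive-fragment scores reproducible across runs.
activity	motif
ACE-inhibitor	AG
ACE-inhibitor	DA
ACE-inhibitor	EV
ACE-inhibitor	GK
ACE-inhibitor	IF
ACE-inhibitor	IP
ACE-inhibitor	IPP
ACE-inhibitor	LE
ACE-inhibitor	PD
ACE-inhibitor	PR
ACE-inhibitor	QQ
ACE-inhibitor	QR
ACE-inhibitor	RL
ACE-inhibitor	SV
ACE-inhibitor	TN
ACE-inhibitor	VE
ACE-inhibitor	VG
ACE-inhibitor	VK
ACE-inhibitor	VP
DPP-IV-inhibitor	DQ
DPP-IV-inhibitor	EP
DPP-IV-inhibitor	GF
DPP-IV-inhibitor	GK
DPP-IV-inhibitor	HV
DPP-IV-inhibitor	IF
DPP-IV-inhibitor	IP
DPP-IV-inhibitor	IT
DPP-IV-inhibitor	LE
DPP-IV-inhibitor	LI
DPP-IV-inhibitor	LM
DPP-IV-inhibitor	LS
DPP-IV-inhibitor	MA
DPP-IV-inhibitor	NV
DPP-IV-inhibitor	PD
DPP-IV-inhibitor	PP
DPP-IV-inhibitor	PR
DPP-IV-inhibitor	PS
DPP-IV-inhibitor	QL
DPP-IV-inhibitor	QQ
DPP-IV-inhibitor	QR
DPP-IV-inhibitor	RL
DPP-IV-inhibitor	SV
DPP-IV-inhibitor	TI
DPP-IV-inhibitor	TN
DPP-IV-inhibitor	VE
DPP-IV-inhibitor	VG
DPP-IV-inhibitor	VH
DPP-IV-inhibitor	VK
DPP-IV-inhibitor	VP
DPP-IV-inhibitor	VV
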