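gene	locus_id	derived_allele	role
ASPM	haplotype_63	D	target
ASPM	A44871G	D	target
ASPM	rs41310927	C	target
ASPM	rs41308365	A	proxy
ASPM	rs3762271	T	proxy
ASPM	rs41304071	T	proxy
ASPM	rs147068597	A	proxy
ASPM	rs61819087	G	proxy
MCPH1	G37995C	C	target
MCPH1	rs930557	C	target
MCPH1	rs1129706	G	proxy
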