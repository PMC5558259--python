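# Default 19-locus CAD risk-score table.
# The locus list (rsids and proxy relations) is fixed; the numeric columns are
# DOCUMENTED PLACEHOLDERS: per-allele log odds ratios and allele labels were not
# redistributable, so synthetic values of realistic magnitude are shipped here.
# Supply a study-specific table for any real analysis.
rsid	effect_allele	other_allele	weight	proxy_for
rs17465637	C	A	0.094
rs9970807	C	T	0.131	rs17114036
rs6725887	C	T	0.115
rs2306374	C	T	0.077
rs12190287	C	G	0.073
rs12204265	A	G	0.061	rs17609940
rs12526453	C	G	0.086
rs11556924	C	T	0.104
rs4977574	G	A	0.198
rs1746048	C	T	0.087
rs2246833	T	C	0.057
rs2505083	C	T	0.063
rs974819	T	C	0.071
rs4773144	G	A	0.068
rs2895811	C	T	0.059
rs7177699	T	G	0.079	rs3825807
rs12449964	C	T	0.066	rs12936587
rs143499	A	G	0.064	rs216172
rs9305545	A	G	0.148	rs9982601
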