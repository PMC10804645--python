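rsid	chrom	pos	ea	oa	eaf	beta	se	pval	n
rs35139284	6	32561370	T	C	0.317	1.759e-04	1.814e-04	0.330	199086
rs35511257	6	32545392	C	G	0.092	5.747e-04	3.115e-04	0.065	199086
rs41270903	6	32629618	G	A	0.180	1.781e-04	2.190e-04	0.420	199086
rs6679677	1	114303808	A	C	0.101	5.343e-04	2.793e-04	0.056	199086
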