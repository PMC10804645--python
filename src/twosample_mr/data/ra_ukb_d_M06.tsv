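rsid	chrom	pos	ea	oa	eaf	beta	se	pval	n
rs35139284	6	32561370	T	C	0.320	0.004	1.615e-04	1.72e-106	361194
rs35511257	6	32545392	C	G	0.095	0.005	2.742e-04	1.29e-60	361194
rs41270903	6	32629618	G	A	0.193	0.002	2.037e-04	3.71e-21	361194
rs6679677	1	114303808	A	C	0.102	0.002	2.475e-04	1.51e-12	361194
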