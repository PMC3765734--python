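species	stage	raw_reads	clean_tags	unique_clean_tags	mapped_unique_tags	genes_hit
H. armigera	embryo	6202369	6058338	97646	71623	22890
H. armigera	larva	5766391	5646953	80673	64679	21080
H. armigera	pupa	6126237	5998625	89193	64458	21987
H. armigera	adult	6021919	5891808	89330	67385	22901
H. assulta	embryo	6072324	5955877	93672	61518	19106
H. assulta	larva	6161560	6048552	88171	60287	19006
H. assulta	pupa	6195186	6084239	88711	55503	18340
H. assulta	adult	5876709	5759082	86860	53283	18705
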