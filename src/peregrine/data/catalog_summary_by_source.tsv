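# Published per-source summary of the assembled enhancer catalog:
# enhancer count and mean element length (bp) for each source set.
source	n_enhancers	mean_length_bp
ENCODE	991173	423
Ensembl	28239	662
FANTOM	65423	281
VISTA	959	2037
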