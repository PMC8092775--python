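# Synthetic modification-frequency fixture: twelve dominant post-translational
# modification types with illustrative counts spanning several orders of
# magnitude. Test scaffolding only; not curated database abundances.
modification	count
disulfide bond	120000
phosphoserine	80000
N-linked glycosylation (GlcNAc) of asparagine	60000
phosphothreonine	30000
N6-acetyllysine	20000
glycyl lysine isopeptide	15000
phosphotyrosine	12000
N6-succinyllysine	8000
N6-(pyridoxal phosphate)lysine	5000
N-acetylalanine	4000
S-palmitoyl cysteine	3000
N-acetylmethionine	2500
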