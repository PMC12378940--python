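level	super_class	pathway	hit_count	pathway_p	enrichment_p	impact	kegg_ids	lcgcms_trend	mr_trend	sig_lcgcms	sig_wgcna	sig_mr	pool_enriched
I	Amino Acid Metabolism	Glycine, serine and threonine metabolism	8	0.005	0.005	0.29	C00065,C00114,C02291,C01005,C00258,C00097,C03508,C00022	up	down	1	1	1	1
I	Amino Acid Metabolism	Cysteine and methionine metabolism	5	0.005	0.005	0.30	C02291,C00065,C00097,C01005,C00022	up	down	1	0	1	1
II	Amino Acid Metabolism	Alanine, aspartate and glutamate metabolism	4	0.005	0.005	0.20	C00041,C00025,C00022,C00042	down	down	1	0	1	1
II	Lipid Metabolism	Glycerophospholipid metabolism	4	0.01	0.14	0.22	C00157,C04230,C00114,C00093	down	down	1	0	1	0
II	Nucleotide Metabolism	Purine metabolism	4	0.01	0.005	0.21	C00385,C00020,C00130,C00387	up	absent	1	1	0	1
III	Amino Acid Metabolism	Glutathione metabolism	4	0.005	0.005	0.04	C00097,C00025,C01879,C00315	up	up	1	0	1	1
III	Vitamin and Cofactor Metabolism	One carbon pool by folate	4	0.005	0.15	0.06	C00114,C00065,C02291,C00097	up	down	1	0	0	0
III	Carbohydrate Metabolism	Butanoate metabolism	2	0.05	0.04	0	C00025,C00042	down	up	0	1	0	0
III	Lipid Metabolism	Sphingolipid metabolism	4	0.005	0.005	0.06	C06124,C00319,C00065,C12144	down	absent	1	0	0	1
III	Amino Acid Metabolism	Arginine and proline metabolism	3	0.005	0.005	0.07	C00315,C00025,C00022	absent	up	0	0	1	1
III*	Lipid Metabolism	alpha-Linolenic acid metabolism	2	0.01	0.03	0.33	C00157,C06427	mixed	absent	1	0	0	1
III*	Carbohydrate Metabolism	Glyoxylate and dicarboxylate metabolism	4	0.005	0.005	0.09	C02557,C00065,C00025,C00258,C00022	up	mixed	1	0	1	1
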