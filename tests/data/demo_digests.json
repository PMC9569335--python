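{
 "active.bed": "ae90bcc969865cc750d3be3f61212c5ed000501da99468d8fc40e47ccddd2f2d",
 "annotation_sizes.json": "9f2c797221dd91f6b9655c5a00103e9aa5f56f979b4e209cd58e76457b626599",
 "cheers_overlaps_disorderA.tsv": "39a4ce56e9cdcfbe12e63afd14abbe19b0f4edffa459b319b8712685edeb8800",
 "cheers_overlaps_disorderB.tsv": "32b89a6813f608591e2af5d4b1ca7f6d1363932bde918fae30b55ed5c1e3beca",
 "cheers_results_disorderA.tsv": "86c1f5c3ebe2d7408a5e976d73502573fa5cd35e333a6a19ae61b46a8508d862",
 "cheers_results_disorderB.tsv": "83da6086975d88814ef4b918d86dcc2af1e4296259f581dd79fb01779f5ca166",
 "conditional_results.tsv": "e9f5865494df22f2b8bed17f1c8ee3f62f634bc14e32fae508f481cd85e52907",
 "correlation.json": "887922b1148c430f044ac19aa499cc78a9d41cd949ebd9e2e6a34d85ba2c32ad",
 "discordant_a_not_b.tsv": "25f62f8a26427022c2e85970cde18403ffd2565f9c4f67168ad5d985a47f5a45",
 "discordant_b_not_a.tsv": "125ee8f97d5ac4fe38c8dec77799031965b0cd68617313b59f105fa117acdd17",
 "enhancer.bed": "adc3714ff4fa07264960ee3bd9d5dd5b98985fd65535bd8b22e3309f59f45cdc",
 "gene_sets.gmt": "e8b97cc16bd909a2bda6568eead4590d478ee5d33ebed67d5c4138b3913fd47c",
 "genes.tsv": "6cb3ed9f540a033f6f99789d2351e23b4c84777956696936b53f949f87041735",
 "genic_enhancer.bed": "c7893dd5bc8c76798d3619b78f8ea2ccc6f9e02f17a06bc6a216d612b14b04bb",
 "genotypes.tsv": "f859dd2dc961718f01067179143d17bc53d06dc8b1858f00753e1407b1d7e868",
 "heritability.tsv": "73b69d90f48d431358f45f2bf483b15db66e9b26b0b87f21293c5f220936b603",
 "ld_scores.tsv": "c32394b4a29476f786322f8e5262dbac473c947959afb426180eb56dd8af38fa",
 "leads_disorderA.bed": "1633cbfd5ebbcac7dd225be1ab50ab27e7455f1740cee9207bc5dc145dfad03e",
 "leads_disorderA.tsv": "092a479e9c951e18d015c9cefb353de3d7d4bcf4aa2e89f2799ecb90208bd992",
 "leads_disorderA_provenance.json": "9162e80a22fac6fb43621c1727df484e0b55ad03fdbfe90811085643ae9710eb",
 "leads_disorderB.bed": "e3b0c44298fc1c149afbf4c8996fb92427ae41e4649b934ca495991b7852b855",
 "leads_disorderB.tsv": "d92692de273e4942d92ab00ff000eb990a097d688664d3d74a07b3214eceb3f4",
 "leads_disorderB_provenance.json": "1fae08747df85d44af257335d7e1aa73ded24877aa087b493897d281d7226ce6",
 "membership.tsv": "2c34834dffbbc1127640c1d176f4af065dea3b8e491ac1eee233b8ba8e6435b5",
 "ora_results.tsv": "b5dbf5f9445c57158e7421a1f35d77ce3655c2698d33304c5314fddf4802d76c",
 "peak_signal.tsv": "401fc8fdb26a6c91eb48f1e41f766dd062d1d6d40b04a1c316c98284ae714663",
 "peaks.bed": "82818b89439e1530d19d61e3466a7c7dcaf5ecc2c53900b58df4dcb554d3a050",
 "planted_leads_disorderA.tsv": "e7727a3de86df4707031e8d739af8441665b4d13752fa06a5c673c92b1b3955f",
 "planted_leads_disorderB.tsv": "d295882faeed1a7eeff3e3e78add85d1664130652d17950321567cb3229a406d",
 "promoter.bed": "158cdb15fe73e94944b646af3bc9952f63577c7ccc2b41c4da8cc42f741ca29b",
 "segmentation.bed": "348200e4428e7179e47389ea581c426e3f49e9e9d77c9ab596329abf1abf81d2",
 "sharing.tsv": "70e56fcd0f99c32539671b11a52d7724feb644d50bcccd12d38f3b8e5b6fc1dd",
 "sldsc_results.tsv": "e8c361c6428b0d69cae39c161d1f2f52d6743f34d578066151f24b18ac18ac63",
 "sumstats_disorderA.tsv": "681b174b8755c083d0a947722d335f886a61c536829e4ccea527a3e9f43e1e44",
 "sumstats_disorderB.tsv": "e3ed7c1e70ecdd4bc1b845b31a9d30d4eba28d907d88f95d043d6b61ccb1dddd",
 "truth.json": "22f42329a6a074913224f12f7872b543a2b9a2be9e10475582dc4df289b68196",
 "variant_map.tsv": "fd6958a36210370e4907a567484c18f83d16f045fe2a36ec11fd7c9f59c65a6e"
}
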