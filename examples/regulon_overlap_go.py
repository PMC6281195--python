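"""Partition three genotypes' regulons into Venn regions and test GO
enrichment of the common core.

Uses small synthetic regulon lists and a toy annotation map; the same code
path handles real gene lists and a genome-wide GO map (background
defaulting to the 33 278 nuclear genes of the reference annotation).
"""

from cbfreg import hypergeometric_enrichment, partition_three_sets

sw = {f"AT{i}G{j:05d}" for i in (1, 2) for j in range(0, 300, 10)}
it = {f"AT{i}G{j:05d}" for i in (1, 3) for j in range(0, 200, 10)}
col = {f"AT{i}G{j:05d}" for i in (1, 2, 3) for j in range(0, 150, 10)}

part = partition_three_sets(sw, it, col, labels=("SW", "IT", "Col-0"))
print(part.to_frame().to_string(index=False))
common = part.regions["abc"]
print(f"\n{len(common)} genes common to all three regulons")

annotation = {
    "GO:0009409": {f"AT1G{j:05d}" for j in range(0, 200, 10)},  # response to cold
    "GO:0009414": {f"AT2G{j:05d}" for j in range(0, 400, 20)},  # water deprivation
}
names = {"GO:0009409": "response to cold",
         "GO:0009414": "response to water deprivation"}
res = hypergeometric_enrichment(common, annotation, background_n=33278,
                                term_names=names)
print("\nGO enrichment of the common core (hypergeometric upper tail):")
print(res.to_string(index=False))
print("\ntarget_pct vs genome_pct shows how concentrated each term is in "
      "the gene set; p is the raw hypergeometric tail probability.")
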