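"""Score CRT/DRE (rCCGAC) motif enrichment in a gene set's promoters.

Builds a synthetic genome in which 44 target genes carry extra planted
motifs, extracts 1-kb promoters from the genome + annotation (round-trip
through the standard coordinate conventions), and tests the target set
against 1000 random same-size gene samples.
"""

from cbfreg import enrichment_test, extract_promoters, observed_per_gene
from cbfreg.simulate import SimulationConfig, generate_promoter_set

config = SimulationConfig(seed=11, n_genes=2000)
targets = [f"G{i:05d}" for i in range(44)]
sim = generate_promoter_set(config, target_genes=targets)

promoters = extract_promoters(sim.genome, sim.models, config.promoter_length)
assert promoters.sequences == sim.promoters.sequences  # coordinate check

res = enrichment_test(promoters, set(targets), n_samples=1000, seed=17,
                      set_label="planted targets (44)")
print(f"{res.set_label}: observed {res.observed_per_gene:.2f} motifs/gene")
print(f"null (1000 random 44-gene samples): "
      f"{res.null_mean:.2f} +/- {res.null_sd:.2f} motifs/gene")
print(f"Z = {res.z:.1f}, empirical P = {res.empirical_p:.2e} "
      f"(normal-tail P = {res.z_tail_p:.1e})")
print("\nbackground occurrence:",
      f"{observed_per_gene(promoters, set(promoters.ids()) - set(targets)):.2f}",
      "motifs/gene")
print("A Z far above 0 with empirical P at the resampling floor (1/1001) "
      "indicates the motif is strongly enriched in the target promoters.")
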