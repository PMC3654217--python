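"""Composition-based binning of contigs from four planted populations.

Tetranucleotide frequency vectors are ordinated by PCA, clustered with
G+C into population bins, screened, and summarized per bin.
"""

from sklearn.metrics import adjusted_rand_score

from thermocomm import binning
from thermocomm.simulate import PopulationSpec, generate_population_genome, shred_contigs

targets = [0.38, 0.48, 0.535, 0.625]
contigs, truth = [], {}
for i, gc in enumerate(targets):
    pop = PopulationSpec(f"pop{i}", 400_000, gc, 2, signature_seed=10 + i)
    genome = generate_population_genome(pop, seed=5)
    recs, _ = shred_contigs(genome, (5000, 20000, 1.0), seed=5)
    contigs += recs
    truth.update({r.id: pop.name for r in recs})

vectors = binning.composition_vectors(contigs, k=4, min_len=5000)
pr = binning.pca_composition(vectors)
assignment = binning.cluster_composition(pr, vectors.meta["gc"], n_bins="auto", seed=0)
assignment = binning.screen_bins(assignment, vectors.meta)
summary = binning.summarize_bins(assignment, vectors.meta)

kept = assignment.kept()
ari = adjusted_rand_score([truth[c] for c in kept.contig_id], kept["bin"])
print(f"{len(vectors.freqs)} contigs, PC1+PC2 variance = "
      f"{pr.explained_variance_ratio[:2].sum():.2f}, ARI vs truth = {ari:.2f}\n")
print(summary.to_string(index=False))
print("\nEach bin's length-weighted G+C (%) recovers one planted population")
print("target (38, 48, 53.5, 62.5); ARI = 1 means a perfect partition.")
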