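"""Per-read G+C profiling with LCA assignment on a two-population mixture.

Builds two populations with contrasting G+C (38% and 62%), shreds reads,
assigns each read from synthetic homology hits pointing at its true genus,
and prints the per-taxon G+C histogram modes.
"""

import numpy as np
import pandas as pd

from thermocomm.reads import TaxonomyTree, assign_reads_lca, gc_taxon_histogram
from thermocomm.simulate import PopulationSpec, generate_population_genome, shred_reads

pops = [
    PopulationSpec("lowGC", 100_000, 0.38, 2, 1,
                   taxon_path=(("domain", "Archaea"), ("genus", "LowGC"))),
    PopulationSpec("highGC", 100_000, 0.62, 2, 2,
                   taxon_path=(("domain", "Archaea"), ("genus", "HighGC"))),
]
tree = TaxonomyTree.from_populations(pops)

reads, hit_rows = [], []
for pop in pops:
    genome = generate_population_genome(pop, seed=11)
    recs, _ = shred_reads(genome, 500, 800, 100, seed=13, id_prefix=pop.name)
    reads += recs
    genus = pop.taxon_path[-1][1]
    hit_rows += [(r.id, f"ref_{genus}", 120.0) for r in recs]

hits = pd.DataFrame(hit_rows, columns=["qseqid", "sseqid", "bitscore"])
taxmap = {"ref_LowGC": "LowGC", "ref_HighGC": "HighGC"}
assignments = assign_reads_lca(hits, tree, taxmap)
hist = gc_taxon_histogram(reads, assignments, tree, subsets=["LowGC", "HighGC"])

print(f"profiled {len(reads)} reads "
      f"({(assignments.status == 'assigned').sum()} assigned)")
for node in ("LowGC", "HighGC"):
    mode = hist.edges[np.argmax(hist.counts[node])]
    print(f"  {node}: histogram mode at {mode:.0f}% G+C "
          f"({hist.counts[node].sum()} reads)")
print("\nThe two modes sit at the planted population G+C targets (38 and 62),")
print("the signal that separates co-occurring populations in a shotgun profile.")
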