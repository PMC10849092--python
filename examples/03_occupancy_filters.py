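"""Orthogroup occupancy filtering with a taxonomic-group scheme.

Loads the bundled (synthetic) 14-group taxonomy, builds toy orthogroups,
and keeps only those represented in at least 10 of the 14 groups — the
kind of selection that reduces millions of raw orthogroups to a densely
sampled core.
"""

import numpy as np

import klebkit as kk
from klebkit.orthology_filters import Orthogroup

taxonomy = kk.load_bundled_taxonomy("groups14")
taxa = list(taxonomy.groups)
rng = np.random.default_rng(11)

orthogroups = []
for i in range(50):
    size = int(rng.integers(3, 30))
    members = tuple(
        (taxa[int(rng.integers(len(taxa)))], f"og{i}_s{j}") for j in range(size)
    )
    orthogroups.append(Orthogroup(id=f"og{i:03d}", members=members))

kept, report = kk.filter_by_group_occupancy(orthogroups, taxonomy, min_groups=10)
print(report.to_frame().to_string(index=False))

kept21, report21 = kk.filter_by_taxon_count(orthogroups, min_taxa=21)
print(f"\nwith a 21-taxon floor instead: {report21.n_kept} of {report21.n_input} kept")
# The group filter asks for breadth across the taxonomy; the taxon-count
# filter asks for depth of sampling. Both partition their input exactly.
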