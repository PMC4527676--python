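"""Percent-identity matrix and 90% redundancy reduction.

Simulates a 13-member globin family, adds three ~97%-identical
near-duplicates of each member (52 rows in all), builds the pairwise
identity matrix from the alignment and reduces it at the 90% threshold.
The greedy sweep keeps exactly one representative per duplicate cluster.
"""

import numpy as np

from globinsp import (
    SequenceRecord,
    SimulationConfig,
    build_matrix,
    random_topology,
    reduce_redundancy,
    simulate_family,
)

rng = np.random.default_rng(0)
tree = random_topology(13, seed=0, branch_length_range=(0.3, 0.8))
family, _ = simulate_family(SimulationConfig(tree, 160, seed=0))

rows = []
for rec in family:
    rows.append(rec)
    for dup in range(3):
        chars = list(rec.sequence)
        for site in rng.choice(len(chars), size=5, replace=False):
            chars[site] = "ACDEFGHIKLMNPQRSTVWY"[rng.integers(20)]
        rows.append(SequenceRecord(f"{rec.id}_dup{dup}", "".join(chars)))

matrix = build_matrix(rows)
off_diag = matrix.values[~np.eye(len(rows), dtype=bool)]
print(f"{len(rows)} sequences; pairwise identity "
      f"{off_diag.min():.0f}-{off_diag.max():.0f}%")

kept = reduce_redundancy(matrix, threshold_pct=90.0)
print(f"kept at 90% identity: {len(kept)} of {len(rows)}")
print("representatives:", ", ".join(kept[:5]), "...")
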