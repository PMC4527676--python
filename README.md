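# globinsp

Globin structure comparison and distance phylogenetics.

Globins are short (~110–160 aa) heme proteins sharing the 3/3 α-helical
myoglobin fold. Placing invertebrate globins — such as the coelomic
hemoglobins of sea cucumbers and brittle stars, or the sea urchin's
14-domain chimeric globin — on the two principal animal globin lineages
(neuroglobin-like vs cytoglobin-like) requires a chain of bespoke
computations around the standard alignment and tree-building tools. This
package implements that chain as a tested, reusable library for molecular
evolution and structural bioinformatics work on globin families:

- **Per-site distance-matrix RMSD (dRMSD)** between aligned Cα traces.
  For structures *A* and *B* sharing *n* aligned columns,

  $$\mathrm{dRMSD}_i(A,B) = \sqrt{\tfrac{1}{n-1}\sum_j \left[d_{ij}(A) - d_{ij}(B)\right]^2}$$

  where $d_{ij}$ is the intramolecular Cα–Cα distance and *j* runs over
  the aligned columns. Comparing internal distances instead of
  coordinates makes the statistic exactly invariant under rigid motion,
  so no superposition has to be chosen. The overall RMSD of a pair is the
  root of the mean squared per-site contribution. Column-wise averaging
  over structure pairs, aligned-region lengths, least-squares (Kabsch)
  superposition for overlays and a structure-guided fallback alignment
  are included.
- **Myoglobin-fold validation**: a candidate aligned to annotated sperm
  whale myoglobin is checked for the invariant proximal F8 histidine,
  coverage of helices B–G, and predominance of hydrophobic residues at
  the ~36 conserved solvent-inaccessible template positions; intron
  locations are translated to helix-relative notation (B12.2, G7.0).
- **Tandem-domain scanning**: iterated masked local alignment
  (BLOSUM62, affine gaps) that decomposes chimeric multidomain globins
  into single domains.
- **Redundancy reduction**: pairwise percent-identity matrices from an
  MSA and a deterministic greedy (Hobohm-1) sweep at an identity
  threshold.
- **Distance phylogenetics**: Poisson-corrected ($d = -\ln(1-p)$)
  pairwise-deletion protein distances, Saitou–Nei neighbor joining
  (exact on additive matrices), bootstrap support and majority-rule
  consensus.
- **Synthetic data**: seed-deterministic generators for families evolved
  on a known tree under a Poisson substitution process, idealised helical
  bundles with controllable noise/rigid motion/deletions, and planted
  multidomain constructions — so every stage is testable without
  downloads.

## Worked example

```python
import numpy as np
from globinsp import (make_helical_template, perturb_structure,
                      StructurePerturbConfig, intra_distances,
                      per_site_drmsd, random_rotation)

template = make_helical_template(8, 19)          # 152-residue bundle
rng = np.random.default_rng(0)
perturbed, truth = perturb_structure(StructurePerturbConfig(
    template, per_site_sigma=0.5,
    rotation=random_rotation(rng), translation=np.array([12., -4., 7.]),
    deletion_spans=[(57, 76)], seed=0))
profile = per_site_drmsd(intra_distances(template),
                         intra_distances(perturbed), truth)
print(profile.n_aligned, round(profile.overall_rmsd, 3))
```

prints `133 0.689`: 133 of 152 columns are aligned (one helix was
deleted, giving 19 gap columns), and 0.5 Å per-site coordinate noise
produces an overall dRMSD of 0.689 Å — the rigid motion contributes
nothing. The `examples/` directory holds one short script per
capability (dRMSD profiles, fold checks and intron notation, tandem
domains, redundancy, NJ + bootstrap, and the two end-to-end workflows);
each prints the numbers it computes and what they mean.

A thin CLI mirrors the library:

```bash
globinsp nj-tree --alignment family.fasta --bootstrap 1000 --seed 1
globinsp struct-rmsd --structures a.pdb --structures b.pdb --target a --out out/
globinsp find-domains --query multidomain.fasta
```

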