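"""Per-site dRMSD between a helical bundle and a noisy, rigidly moved copy.

Builds an idealised 8-helix C-alpha bundle, perturbs it with 0.5 Å
isotropic noise plus a random rigid motion and a deleted helix, and
compares the two structures through their internal distance matrices.
Because dRMSD works on intramolecular distances, the rigid motion
contributes nothing: the profile reflects only the noise, and the deleted
helix shows up as a block of gap columns.
"""

import numpy as np

from globinsp import (
    StructurePerturbConfig,
    intra_distances,
    make_helical_template,
    per_site_drmsd,
    perturb_structure,
    random_rotation,
)

template = make_helical_template(8, 19)
rng = np.random.default_rng(0)
perturbed, truth = perturb_structure(
    StructurePerturbConfig(
        template,
        per_site_sigma=0.5,
        rotation=random_rotation(rng),
        translation=np.array([12.0, -4.0, 7.0]),
        deletion_spans=[(57, 76)],  # helix 4 removed
        seed=0,
    )
)

profile = per_site_drmsd(intra_distances(template),
                         intra_distances(perturbed), truth)
print(f"columns: {profile.n_columns}, aligned: {profile.n_aligned}, "
      f"gap columns: {int(profile.gap_mask.sum())}")
print(f"overall dRMSD: {profile.overall_rmsd:.3f} A "
      f"(0.5 A per-site noise; rigid motion does not contribute)")
print(f"per-site range: {np.nanmin(profile.values):.3f} - "
      f"{np.nanmax(profile.values):.3f} A")
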