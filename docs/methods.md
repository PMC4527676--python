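# Methods

This note documents the models and procedures the package implements, the
parameters that matter, the synthetic-data assumptions, and the places
where the design was genuinely open.

## Per-site distance-matrix RMSD (struct_compare)

For two Cα traces *A* and *B* joined by a column-wise alignment with *n*
columns aligned in both, the per-site statistic at aligned column *i* is

    dRMSD_i(A,B) = sqrt( 1/(n-1) * Σ_j [ d_ij(A) − d_ij(B) ]² ),

with d_ij the intramolecular Cα–Cα distance and the sum over all *n*
aligned columns *j*. The j = i term is included: it contributes exactly
zero (d_ii = 0), so inclusion or exclusion is immaterial while keeping the
normalisation 1/(n−1) an honest average over the n−1 informative terms.
Columns gapped in either structure carry no value and are flagged as gaps.
The statistic is a function of the two intra-structure distance matrices
only, hence exactly invariant under any rigid motion (and under reflection
— a deliberate property of distance-based comparison). It is symmetric in
A and B, and zero for every site iff the two distance submatrices over the
aligned columns are identical.

The **overall RMSD** of a pair is reported as
sqrt(mean_i dRMSD_i²) — a root is applied to the mean of squared per-site
contributions so the summary lives on the same Å axis as the profile. The
literal mean-of-squares is available via `sqrt_overall=False`; the
distinction only matters when comparing against summaries whose convention
is unknown. Averaged profiles over two structure pairs are computed
pairwise-then-averaged per column (gap in either input ⇒ gap in the
output), carrying the mean of the two overall values.

**Superposition** is classical least-squares (Kabsch, SVD with the proper
rotation enforced; reflections excluded), requiring ≥3 non-collinear
aligned pairs. It is provided for producing overlays, not for the dRMSD
itself, which needs none.

**Structure-guided fallback alignment.** When no externally computed
alignment is available, a pairwise mapping to a reference trace is built
by seeding correspondences with a global BLOSUM62 sequence alignment,
superposing, then re-pairing monotonically to the nearest Cα within 5 Å
and iterating to convergence (≤3 rounds). Multiple structures are aligned
progressively against the first trace; columns are the reference residues.
This is a pragmatic stand-in for a sampled consensus alignment; any number
derived from it should state that the alignment was structure-guided.
Results on real structure sets depend noticeably on this choice, which is
why the integration checks on published structures use ordering claims and
generous tolerances.

## Myoglobin-fold validation (globin_fold)

The fold template is an ordered list of helix-relative positions. The
default list has 36 positions (33 intra-helical on helices A–H, the
inter-helical CD1 and FG4, and the invariant F8); an alternate 37-position
variant (C5 for C4, plus CD4) is selectable with `variant="s1fig"`. The
shipped reference is the mature 153-residue sperm whale myoglobin chain
with standard helix boundaries (A 3–18, B 20–35, C 36–42, CD 43–49,
D 51–57, E 58–77, EF 78–85, F 86–94, FG 95–99, G 100–118, GH 119–124,
H 125–148), under which F8 = His93, E7 = His64 and CD1 = Phe43 — asserted
in the test suite.

Verdict rule: **pass** iff (i) the candidate residue aligned to F8 is His;
(ii) each of helices B, C, E, F and G has candidate residues at ≥50% of
its template positions — helix D is not required because genuine globins
exist in which D is absent or disordered; (iii) unless `strict=True`, the
fraction of template positions holding a hydrophobic residue
({A,C,F,I,L,M,V,W,Y}; X never counts) is ≥0.70 ("predominantly"
hydrophobic — the reference itself scores 0.75, so demanding much more
would reject the defining structure); and (iv) when a structure-profile
compatibility Z-score is supplied as metadata, it exceeds 6. Strict mode
applies only (i), (ii) and (iv), for use when the hydrophobicity pattern
should be descriptive rather than gating. The check reads residues
through alignment-column lookups by residue ordinal, so it is invariant
under padding with all-gap columns, and removing a helix can only remove
evidence — a fail can never become a pass.

**Intron notation.** A coding-sequence nucleotide offset o (1 ≤ o < 3L)
maps to residue ⌊o/3⌋+1 and phase o mod 3; phase 0 denotes an intron
between codons and names the following residue, so an intron between the
codons of helix-G residues 6 and 7 is G7.0, and one after the second
nucleotide of the helix-B residue-12 codon is B12.2. The candidate residue
is translated to the reference's helix-relative label through the
alignment; positions outside annotated segments report pre-A/post-H, and
candidate residues aligned to a reference gap report "unaligned".

## Tandem-domain scan (domain_scan)

Local alignment of a single-domain probe against the query (BLOSUM62,
gap open 11 / extend 1 — the standard protein defaults), iterated: the
best hit with score ≥ `min_score` (default 60) is accepted, its span is
removed from further consideration by splitting the search interval, and
scanning continues inside the remaining segments until no hit reaches the
threshold. Interval splitting makes overlap impossible by construction;
equal scores resolve to the leftmost start, so the scan is deterministic.
Calls are trimmed to the probe-covered span and must fall within
[`min_len`, `max_len`] = [90, 180] residues, the plausible single-globin
range. With the shipped myoglobin probe, each call also reports whether
the query residue aligned to the probe's F8 position is His. The
boundaries of real multidomain proteins are not sharply defined;
agreement in call count and approximate span is the intended contract,
verified on planted constructions with up to 20% point mutations.

## Redundancy reduction (redundancy)

Percent identity between two MSA rows is 100 × (identical pairs) /
(comparable columns), where a column is comparable iff both rows are
non-gap; a variant using the full alignment length as denominator is
available (`denominator="alignment"`). Pairs with no comparable column are
missing values. Reduction is a Hobohm-1 greedy sweep in input order: keep
a sequence iff its identity to every previously kept sequence is strictly
below the threshold (default 90%). Missing values never force removal.
The kept set is always independent (all kept pairs below threshold) and
maximal (every removed row has a kept neighbour at/above threshold).
Input-order greed is deterministic, but it is *not* threshold-monotone on
adversarial inputs: a mid-level neighbour that a low threshold removes can
survive a high threshold and then displace later rows. On
cluster-structured similarity data — tight near-duplicate groups over a
dissimilar background, the regime redundancy reduction is used for —
raising the threshold only grows the kept set; both facts are covered by
tests.

## Distance phylogenetics (phylo_nj)

p-distances use **pairwise deletion**: for each pair, columns with a gap
or X in either row are excluded; the distance is differing/comparable
columns. The **Poisson correction** d = −ln(1−p) inverts the expected
relation between elapsed substitutions and observed differences under a
Poisson process in which every substitution lands on a new state; p = 1 is
a saturated comparison and raises an error rather than yielding infinity.
**Neighbor joining** is the standard Saitou–Nei agglomeration on the Q
criterion; ties resolve to the lexicographically lowest index pair, and
negative branch-length estimates are clamped to zero with the deficit
logged. NJ is exact on additive matrices, which the tests verify to 1e-9
against trees the generator constructed. **Bootstrap** resamples columns
with replacement, reruns the whole distance/NJ pipeline per replicate and
reports, for each internal branch of the full-data tree, the percentage of
valid replicates containing its bipartition; replicates with a saturated
or empty pairwise comparison are dropped and counted in the log (default
seed 1234; an alignment with no variation is an error). **Majority-rule
consensus** keeps bipartitions present in strictly more than half of the
input trees — such splits are mutually compatible by counting — and
labels them with their frequency percent.

Model-based tree inference (likelihood or Bayesian, rate heterogeneity,
empirical substitution matrices) is deliberately out of scope; this module
covers only the distance stage.

## Synthetic data (synthetic_data)

`simulate_family` evolves sites independently down a given tree: per
branch of length b, the substitution count per site is Poisson(b) and each
substitution replaces the residue with a uniformly chosen different amino
acid. This 20-state uniform-replacement regime is exactly the model whose
expectation the Poisson correction inverts (up to the finite-alphabet
back-substitution term, <1% bias for path lengths ≤0.3), which closes the
loop for the NJ parameter-recovery tests. Defaults used throughout testing
are 8 taxa, 2000 sites and branch lengths drawn uniformly from
[0.05, 0.3] substitutions/site — a moderately diverged family in which
topology recovery should be near-certain, chosen to make recovery failures
informative about code rather than about statistics. What the generator
does *not* model: indel evolution, among-site rate variation, amino-acid
exchangeability structure, and compositional bias; passing tests therefore
demonstrate algorithmic correctness in the assumed regime, not robustness
to real-data violations of it.

`make_helical_template` builds ideal α-helices (1.5 Å rise and 100°/residue
about the axis, Cα radius 2.3 Å ⇒ consecutive Cα separation ≈3.8 Å) packed
antiparallel on a circular bundle of radius 8 Å; 8 helices × 19 residues
give a 152-residue single-domain-sized trace. `perturb_structure` adds
isotropic Gaussian per-site noise (no correlated backbone modes), an
optional rigid motion, and deletion spans, returning the ground-truth
column mapping; with σ = 0.5 Å the overall dRMSD against the template
concentrates around 0.7 Å. `make_multidomain` concatenates mutated copies
of a domain with GS linkers and reports the planted intervals.
All generators are seed-deterministic.

## Workflows, numerical choices, limitations

The sequence workflow (fold check → domain scan → redundancy → NJ with
bootstrap) and structure workflow (distances → per-pair profiles → average
→ superposition) write TSV/FASTA/Newick/JSON outputs plus a manifest with
input SHA-256 digests, parameters and the single seed from which all
randomness flows; deterministic outputs are byte-identical across reruns.
Floats in TSV outputs carry 4 decimals; Newick branch lengths 6
significant digits; supports are written as integer internal-node labels.
PDB reading takes the first model only, resolves alternate locations to
the highest occupancy (ties: first encountered), skips HETATM records
except selenomethionine (read as Met), and maps non-standard residues to
X. Multi-chain entries default to the first chain containing Cα atoms,
overridable per structure — which chain a published analysis used is often
unstated, so chain choice is surfaced as a parameter rather than guessed.

Known limitations: the structure-guided fallback alignment is greedy and
reference-anchored, so consensus alignments from joint samplers will
differ from it in detail; bootstrap drop-and-log handling of
saturated replicates is a policy choice, not a community standard; and
the fold check evaluates candidates against a single annotated reference
rather than a profile.
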