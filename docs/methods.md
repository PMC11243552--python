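# Methods

## Scope and data flow

bindscape operates downstream of external engines: docking scores and
energy decompositions, RMSF profiles from molecular dynamics, and
crystallographic coordinates are *inputs*. The toolkit's own
computations are (i) molecular similarity over the designed ligand
library, (ii) geometric contact detection in 3D complexes, (iii)
binding-mode fingerprint comparison, (iv) the affinity-landscape
indices and cliff detection, and (v) flexibility difference maps.
Nothing here re-docks, re-simulates or re-refines.

## The designed library

The library crosses ten halogenation patterns of the benzimidazole
4–7 positions (tetra-Br/Cl/I; 5,6-di-Br/Cl/I; and the four mixed
5,6-di-X + 4,7-di-Y patterns) with four N(1) glycone options (none,
ribose, 2′-deoxyribose, 2′-deoxy-2′,2′-difluoro-ribose), giving 40
ligands with deterministic ids `<pattern>_<series>`
(e.g. `4567-tetraBr_difluoro`). These ids are the join key between
SMILES structures and the rows of the packaged docking tables.
Generated SMILES carry no stereocenters on the sugar; similarity
measures used here are insensitive to that, and conformer generation
beyond a single embedded geometry is out of scope.

## Similarity measures

Proprietary fragment-sphere and 3D-pharmacophore descriptors have no
published closed form, so the toolkit ships two open equivalents and an
escape hatch:

* **circular**: Morgan fingerprints, radius 2, 2048 bits (community
  standard resolution), Tanimoto similarity on bit sets;
* **feature_pair**: unordered pairs of pharmacophore features (donor,
  acceptor, aromatic ring centroid, hydrophobic carbon, halogen) with
  the inter-feature distance binned at 2 Å from 0 to 12 Å. The bit
  space is enumerable (15 type pairs × 6 bins = 90 bits), so no hash
  collisions. Without a conformer, topological shortest paths scaled by
  1.5 Å/bond stand in for Euclidean distances; aromatic features then
  use a representative ring atom.
* **external**: any similarity matrix as CSV, so descriptors computed
  elsewhere plug into the landscape unchanged.

The Tanimoto of two empty fingerprints is defined as 1 (identical
absence) and logged as a warning: the 0/0 case signals degenerate
input, not dissimilarity. Exact numerical agreement with the
proprietary descriptors is a non-goal; the landscape methodology is
independent of the specific similarity used.

## Contact detection

The interaction reports this toolkit emulates come from crystallographic
analysis whose numeric criteria are not published. Defaults were chosen
so that every geometry in that family of reports falls inside the
envelope, and all are keyword-configurable:

| interaction | distance | angle |
|---|---|---|
| H-bond, strong | D⋯A ≤ 3.6 Å | D–H⋯A ≥ 120° |
| H-bond, weak envelope | D⋯A ≤ 4.1 Å | ≥ 90° |
| halogen bond (Cl/Br/I) | X⋯A ≤ 3.8 Å | C–X⋯A ≥ 140° |
| hydrophobic | C⋯C ≤ 4.0 Å | — |

The weak envelope deliberately covers long N–H⋯Cl (3.95 Å) and highly
non-linear O–H⋯O (3.81 Å, 102°) bonds. Fluorine is excluded as a
halogen-bond donor (no appreciable σ-hole) but accepted as a weak
H-bond acceptor. Apolar carbons are carbons with no N/O/S within
covalent range (1.85 Å); hydrophobic contacts aggregate to one record
per (ligand atom, residue) at minimum distance.

Hydrogen handling is deterministic: explicit hydrogens within 1.25 Å of
a donor give the true D–H⋯A angle (most linear H wins); without
hydrogens the angle falls back to the heavy-atom surrogate
(antecedent–donor⋯acceptor), using a per-residue antecedent table for
protein donors and the nearest bonded heavy atom for ligand donors. No
protonation tool is invoked. Waters and metals are excluded by default;
alternate locations resolve to highest occupancy, ties by altloc
letter.

Neighbor search uses a k-d tree; the test suite pins it to an all-pairs
brute-force oracle and checks invariance under rigid rotation and
translation (1e-6 Å / deg) and detection boundaries at cutoff ± 1e-3.

## Binding-mode comparison

Fingerprints align on the union of keys with absent entries as zero —
a residue that is not contacted contributes no energy, matching how
heatmaps render absent interactions at the weak end of the scale.
`rmsd_bm` equals the Euclidean distance divided by √n (an identity the
tests exercise on random fingerprints). The "additive" distance is the
signed sum Σ(pᵢ−qᵢ): it reports the *balance* of contributions, and its
sign says which mode binds more strongly overall; |additive| ≤
Manhattan always. Residue ranking uses mean |strength| because
energies are negative and "strongest" orders by magnitude; ties break
lexicographically so output is deterministic.

Energy tables are ingested with tolerant headers (unicode minus and
prime marks normalized, `Hydrogen Bond`/`Hydrogen Bonds` both accepted)
because published tables routinely use typographic minus signs. The
packaged CK2α/PIM-1/RIO1 tables are stored exactly as printed
(unicode minus included) with a provenance column, and their sha256
checksums are pinned; a failed pin aborts the load.

## Landscape analysis

`sali` and `sbai` are the same functional |Δv|/(1−s); they are kept as
separate entry points because activity (e.g. K_i) and binding affinity
(kcal/mol) live on different scales and should not be mixed in one
column. Values are used as provided — no log transform is applied to
K_i-scale activities unless the caller does so, since the index is
scale-agnostic.

At s = 1 with Δv ≠ 0 the index is infinite. The infinity is carried as
a real `inf` sentinel (ranking is sentinel-aware) alongside a finite
capped value, default cap 2000, used for display and node sizing — the
truncation exists for clarity only and never reorders non-capped pairs.

Graph construction: edges where s ≥ threshold (default 0.65, a
conventional similarity-network cutoff; no canonical value exists, so
it is config-exposed), node score aggregating the capped index over
incident edges. `max_index` is the default because it highlights a
node's worst cliff partner, which is the point of cliff spotting;
`mean_index` is available. Isolated nodes persist with score 0.

## Flexibility

"Normalized B-factor" is the per-chain z-score with population
standard deviation — standard crystallographic practice, and consistent
with difference maps whose color scales span a few units around zero.
Normalization refuses constant profiles rather than emitting NaN.
Difference maps match residues across structures by (chain, residue
number) only; a structural alignment between organisms is out of scope,
and an offset map can be supplied upstream when numbering differs.
RMSF profiles are ingested from CSV; the coarse-grained simulations
that produce them are not reimplemented.

## Synthetic fixtures

`synth_complex` places each planted contact in its own residue unit,
25 Å from the others (far beyond any cutoff), so detected contacts map
one-to-one onto the spec. Geometry is solved in closed form (sine rule
for the H position given the D⋯A distance and D–H⋯A angle), so the
in-memory structure reproduces the planted values to machine precision;
the written PDB rounds to the format's 3 decimals, which preserves
detection classes across a write/read round trip. The protein side uses
Ala/Leu/Val/Asn-style scaffolds so backbone oxygens, apolar side-chain
carbons and H-bond partners are all available.

`synth_landscape` draws background pair similarities and ligand
affinities uniformly from configured ranges (defaults: s ∈ [0.1, 0.5],
BA ∈ [−9.6, −5.8] kcal/mol, matching the spread of the packaged CK2α
affinities) with a seeded generator. Cliff k occupies the ligand pair
(2k, 2k+1) and is realized exactly at the requested (s, ΔBA); a cliff
whose similarity does not exceed the background ceiling is rejected as
unseparable. What passing tests show: the detection machinery recovers
plants perfectly under these idealized conditions. What they do not
show: performance on real docking noise, correlated similarities, or
cliff pairs embedded inside dense similarity clusters.

## Numerical and interface choices

* Acos arguments are clamped to [−1, 1]; angles are reported in
  degrees in [0, 180].
* Heatmap CSV export writes `repr(float)` so re-import is bit-exact
  (pandas reads with `float_precision="round_trip"`).
* Problem sizes in tests and the acceptance script (2000-atom oracle
  complexes, 30-ligand synthetic landscapes, the 40-ligand packaged
  table) keep every check fast while covering all code paths.
* CLI exit codes: 0 success, 1 usage error, 2 data error. Config
  precedence is flag > config file > built-in default.

## Known limitations

* Contact typing is heuristic (no bond orders in PDB input): donor /
  acceptor assignment for non-standard residues relies on explicit
  hydrogens or element rules.
* π-stacking and ionic interactions are not detected; water bridges
  only via the opt-in water retention flag.
* Exact reproduction of any specific renderer's network layouts or of
  proprietary descriptor values is not attempted.
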