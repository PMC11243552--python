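# bindscape

A toolkit for the quantitative side of structure-based ligand tuning:
given a congeneric ligand series (here, polyhalogenated
1*H*-benzimidazoles and their ribose / 2′-deoxyribose /
2′-deoxy-2′,2′-difluoro-ribose nucleosides docked against the kinases
CK2α, PIM-1 and RIO1), it answers the questions a medicinal chemist asks
between docking runs and synthesis:

* **Which small structural change buys the most affinity?**
  Structure–activity / structure–binding-affinity landscape indices over
  all ligand pairs, with activity-cliff detection and network-like
  similarity graphs.
* **Do two ligands bind the same way?** Binding-mode fingerprints
  (per-residue or per-ligand-atom interaction strengths) compared with a
  binding-mode RMSD and Manhattan / Euclidean / signed-additive
  distances, rendered as ranked heatmaps.
* **What holds the ligand in place?** Geometric detection of hydrogen
  bonds, halogen bonds and hydrophobic contacts in PDB complexes, with
  exact distance/angle measurement.
* **Does binding rigidify the target?** Normalized B-factor and RMSF
  profiles and per-residue difference maps between complexes.

## The indices

For ligands 1 and 2 with structural similarity *s* ∈ [0, 1] (Tanimoto
over circular fingerprints, a pharmacophore feature-pair descriptor, or
an externally supplied matrix):

```
SALI = |A₁ − A₂| / (1 − s)          (experimental activity A)
SBAI = |BA₁ − BA₂| / (1 − s)        (docked binding affinity BA, kcal/mol)
```

Both diverge as *s* → 1 at fixed value difference: a pair of
near-identical ligands with very different affinity — an *activity
cliff* — dominates the landscape. SBAI is the screening-stage analogue
of SALI for when experimental activities are not yet available.

Binding modes P = {pᵢ}, Q = {qᵢ} (interaction strength per residue,
aligned on the union of contacted residues, absent contacts = 0) are
compared with

```
RMSD_BM(P, Q) = sqrt( (1/n) Σᵢ (pᵢ − qᵢ)² )
```

which is the Euclidean distance scaled by 1/√n, so it stays comparable
across binding sites of different size.

## Worked example

The packaged CK2α docking table (40 ligands: 10 halogenation patterns ×
4 glycone series) drives the whole affinity landscape from the shell:

```
$ bindscape landscape --table ck2a --cap 2000 -o out/
780 pairs, 1 cliffs, 63 graph edges -> out
```

780 = 40·39/2 ligand pairs, each with similarity, affinity difference
and capped SBAI (`out/pairs.csv`); the similarity graph with per-node
cliff scores is written as GraphML. In Python, the headline numbers:

```python
>>> from bindscape import binding_mode as bm, landscape as ls, fixtures
>>> ck2a = fixtures.load_packaged_tables("ck2a")
>>> bm.series_extremum(ck2a, series="difluoro")
('4,5,6,7-tetraiodo-', -9.59)
>>> ls.sbai(-8.67, -9.59, 0.0)   # parental vs difluoro tetraiodo, s = 0
0.92
```

The gem-difluoro sugar is what the landscape flags: swapping the bare
benzimidazole (−8.67 kcal/mol) for its 2′,2′-difluoro nucleoside gains
almost 1 kcal/mol, and at higher structural similarity the same ΔBA
produces a proportionally larger SBAI (at *s* = 0.5 it would read 1.84).

Contact profiling runs on any PDB complex; on a synthetic complex with
planted interactions it reads back the planted geometry exactly:

```
$ bindscape simulate complex -o out/ && bindscape profile out/synthetic.pdb --ligand LIG -o out/
$ cat out/contacts.tsv
kind            ligand_atom  residue   distance  angle    class
hbond           N1           ASN10/A   3.140     165.03   strong
halogen_bond    BR2          VAL11/A   3.000     172.68   strong
hydrophobic     C3           LEU12/A   3.900              strong
```

## Layout

| module | contents |
|---|---|
| `bindscape.ligands` | designed library, fingerprints, similarity matrices |
| `bindscape.interactions` | PDB loading, H-bond / halogen-bond / hydrophobic detection |
| `bindscape.binding_mode` | fingerprints, RMSD_BM, metrics, heatmaps, table ingestion |
| `bindscape.landscape` | SALI/SBAI, pairwise landscape, cliffs, graphs, index surface |
| `bindscape.flexibility` | B-factor/RMSF profiles, normalization, difference maps |
| `bindscape.fixtures` | planted-contact complexes, planted-cliff landscapes, packaged tables |
| `bindscape.cli` | `bindscape` command (`profile`, `compare`, `landscape`, `surface`, `flex`, `simulate`) |

See `docs/methods.md` for the model assumptions, default criteria and
their rationale, and known limitations.
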