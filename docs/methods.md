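# Methods

## Problem and definitions

Given a table of compound–target activity measurements, the package
identifies *single-atom-modification activity cliffs* (sam_ACs): unordered
pairs of compounds that (i) are identical except for one heavy atom and
(ii) differ in potency by at least 100-fold against the same target under
the same measurement type.

Structural identity is decided on standardized molecular graphs keyed by
canonical SMILES. Two single-atom relations are recognized, both restricted
to the four element swaps N-C, O-C, N-O and S-O:

* **atom replacement (ar)** — compound B equals compound A with the element
  at one position substituted; heavy-atom formulas differ by exactly one
  decrement/increment within the swap;
* **atom walk (aw)** — A and B have identical formulas and differ only in
  the position of one heteroatom: A carries X at position *i* and Y at *j*,
  B carries Y at *i* and X at *j*, with {X, Y} an admissible swap.

Potency is expressed as pPot = −log10(value in mol/L) (pKi or pIC50); the
cliff criterion is ΔpPot ≥ 2.0, inclusive at the boundary, evaluated at
full floating-point precision with no slack.

## Standardization

`standardize` parses a SMILES, keeps the largest organic fragment (ties
broken by canonical SMILES so the choice is stable), clears isotope
labels, neutralizes charges where RDKit's uncharger finds a sensible
neutral form, re-perceives aromaticity and emits the canonical SMILES as
the molecule's key. Hydrogens are implicit throughout — a single-atom
modification concerns heavy atoms, and the accompanying hydrogen-count
change (ring N with no H vs. ring CH) is accepted by construction.

Stereochemistry is *retained* in canonical keys by default: two compounds
differing in a stereocenter in addition to the atom modification do not
pair, reading "only distinguished by a single atom" strictly. This is
configurable (`keep_stereo=False`) because component databases are
inconsistent about stereo annotation.

Compounds that remain charged after neutralization keep the charge in
their key; since mutation preserves formal charge, charged compounds only
pair with equal-charge analogs, preventing charge artifacts from
masquerading as atom swaps.

## Single-atom mutation

`mutate_atom` kekulizes the graph (clearing aromatic flags), substitutes
the element, resets the explicit-hydrogen count, and re-sanitizes so that
implicit hydrogens and aromaticity are re-derived rather than patched —
pyridine → benzene changes aromatic perception and must be recomputed.
Stereo descriptors invalidated by the substitution are dropped
(`AssignStereochemistry(cleanIt=True)`), the rest retained. A mutant that
fails valence sanitization does not exist (e.g. O in place of a
quaternary N⁺); callers treat this as "no such analog".

## Pair detection: the mutant-key join

All valence-valid mutants of all compounds are indexed by (mutant canonical
key, directed swap). Then:

* **ar**: a pair (A, B) exists iff some mutant key of A equals B's own key.
* **aw**: (A, B) is an aw pair iff both produce the *same* mutant key under
  the *same* directed swap Y→X at different positions. Proof sketch of
  equivalence with the positional-exchange definition: if A has X at *i*
  and Y at *j* while B has Y at *i* and X at *j*, mutating each one's Y to
  X yields the common all-X intermediate M, so they share a mutant.
  Conversely, if A ≠ B share mutant M under Y→X, each equals M with one X
  reverted to Y at distinct positions of M, which is exactly the exchange
  relation. Symmetry-equivalent exchange sites would make A and B the same
  structure, which the duplicate-structure precondition excludes.

Cost is linear in the total number of (atom, applicable swap) mutations,
versus quadratic all-pairs graph comparison. The test suite certifies
exact agreement with a brute-force oracle (`oracle_pairs`, exhaustive
single mutation plus exhaustive position-pair exchange, bounded at 14
heavy atoms) on 200 seeded random batches and on every generated fixture.

Pairs are stored unordered (lexicographic compound-ID order), once per
distinct swap label; when symmetric molecules admit the same relation at
several sites, the lowest canonical site ranks are kept so outputs are
bit-stable. Site annotations are excluded from pair equality.

## Curation rules and their order

Records pass, in this order: organism = *Homo sapiens*; target type =
single protein; assay relationship = "D"; confidence = 9; measurement ∈
{Ki, IC50}; relation = "="; unit ∈ {nM, µM, M}; value positive and
finite; structure standardizes with ≥ 4 heavy atoms after salt stripping.
A failing record is tallied under its *first* failing criterion, making
exclusion tallies deterministic; |kept| + Σ tally = |input| always holds.
The 4-heavy-atom floor is applied at curation (not inside `standardize`)
so the structural primitive stays usable for arbitrary fragments.

Replicate aggregation takes the arithmetic mean of per-record p-values
(the geometric mean of molar values) per (compound, target, measurement)
group. Groups whose p-values span more than 1.0 log unit are discarded
wholesale: a 100-fold cliff call should not hinge on replicates that
disagree by more than 10-fold. Both the mean rule and the 1.0 span cutoff
(inclusive) are configurable; summation runs over sorted values so the
mean is bit-identical under record reordering. Ki- and IC50-derived
potencies are kept in disjoint subsets end to end because the two
measurement types are not directly comparable.

## Cliff calling and output

`call_cliffs` selects target-based pairs with ΔpPot ≥ log10(fold), fold
defaulting to 100. The output row schema lists, in order: both compound
IDs, both canonical SMILES, measurement type, both p-values, target name /
UniProt / ChEMBL ID, target class and group, sam_AC type (`ar_AC`/`aw_AC`),
modification type, and PDB ID(s). The weaker analog occupies the first
column block (ordering configurable in code); PDB IDs are
semicolon-separated, the field left empty when no structure matches.
`read_dataset` inverts `write_dataset` exactly; p-values are serialized
with `repr` so floats round-trip bit-exactly.

## X-ray association

Local tables map ChEMBL target IDs to UniProt accessions and PDB entries
(`target_chembl_id,uniprot,pdb_id` rows) and PDB entries to co-crystallized
small-molecule ligands (`pdb_id,ligand_code,smiles`). A structure is
attached to a cliff when it is reachable from the cliff's target mapping
and one of its ligands is canonically identical to an analog. Matching is
stereo-insensitive by default — chemical-component records frequently omit
or re-derive stereocenters — with a strict mode available; attached IDs are
sorted, and each carries a role annotation ("potent", "weak" or "both")
saying which analog is co-crystallized. Whether a mapped entry's ligand
binds the mapped chain specifically is the table producer's responsibility.
No network access occurs anywhere in the package.

## Synthetic fixtures

The generator emulates the input shape of a ChEMBL extract at desk scale.
Each series is built from an aromatic scaffold (substituted benzene with a
swap-specific tail: alkyl for N-C and O-C series, diamine for N-O, diether
for S-O): the base compound plus two single-atom mutants under the same
directed swap, giving two ar pairs and one aw pair whose ground truth is
computed by the exhaustive oracle, not assumed. Cross-series pairing is
structurally impossible because every series gets a unique (heavy-atom
count, halogen multiset) signature — any analog pair must agree on both —
and this is re-certified at generation time by a mutant-key contact check
that aborts on any unplanned relation. Decoys are iodoalkanes of distinct
sizes; no series compound contains iodine.

Potencies are planted with deterministic margins around the 2.0 boundary:
a *cliff series* places its compounds on a ladder with 3.0 log-unit rungs
(every within-series pair ≥ 3.0 apart, base drawn uniformly from
pKi 4.0–5.5); a *non-cliff series* jitters all compounds within ±0.2 of a
common value (pair deltas ≤ 0.4). Each compound yields 1–3 replicate
records with Gaussian noise (sd 0.2 on the p-scale, clipped at ±0.45 and
re-centered per compound), so the aggregated mean equals the planted value
exactly, the replicate span never triggers the 1.0 discard rule, and
planted-truth recovery is exact rather than probabilistic. A configurable
fraction of cliff series gets mapping/ligand tables co-crystallizing the
most potent series compound (occasionally also the weakest, emulating the
rare both-analog case). Ten additional records violate one curation
criterion each, exercising every exclusion path. All randomness derives
from one integer seed; fixed seed ⇒ byte-identical CSVs.

What the fixtures do *not* emulate: realistic potency distributions per
target family, assay noise that correlates with potency, chemical diversity
beyond what pair detection requires (the scaffolds are deliberately small
and regular), structural duplicates across compound IDs, and ligand tables
polluted with ions or polymers. Passing the planted-truth tests therefore
demonstrates correctness of the detection and calling logic under the
stated definitions, not robustness to every artifact of real extracts; the
curation rules handle the standard artifacts (salts, charges, isotopes,
bad units, non-exact relations) and are tested on them directly.

## Problem sizes

The certification suite runs the oracle comparison on 200 batches of 10–60
molecules (≤ 14 heavy atoms) and the recovery test on 50-series fixtures
under three seeds; `scripts/acceptance.py` uses a 50-series fixture, 60
oracle batches and 1000 synthetic cliffs for the round-trip check. These
sizes exercise every code path and swap type while keeping a full run in
the tens of seconds; they are not statistical estimates, so larger sizes
would add runtime, not information.

## Numerical and degenerate-input choices

* The 100-fold boundary is inclusive and computed on full-precision
  p-values; ties at exactly 2.0 are cliffs.
* Unit conversion accepts nM, µM (also spelled uM) and M; anything else is
  an `UnknownUnits` exclusion, never a guess.
* Empty pair or cliff lists flow through every stage and writer without
  error.
* Duplicate structures (same canonical key, different compound IDs) are a
  hard error in pair enumeration; the pipeline pre-deduplicates by keeping
  the lexicographically smallest ID and logging the rest.
* Deterministic tie-breaks everywhere: sorted outputs, lowest canonical
  site ranks, lexicographic PDB IDs.

## Known limitations

* Tautomers are not canonicalized; two tautomeric drawings of the same
  compound have different keys and will not pair.
* The strict-stereo default means a compound pair differing by one atom
  *and* a stereocenter is not reported, even though a chemist might accept
  it; relax with `keep_stereo=False`.
* Ligand matching is whole-molecule identity on component SMILES; covalent
  adducts or partially resolved ligands in real PDB entries will not match
  their parent compound.
* The exhaustive oracle is limited to 14 heavy atoms by design; it is a
  verification device, not a production path.
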