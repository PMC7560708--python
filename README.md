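# samcliff

**Activity cliffs produced by single-atom modifications, from curated
compound-activity data to X-ray-supported cliff tables.**

An *activity cliff* (AC) is a pair of structurally analogous active
compounds with a large potency difference — here, at least 100-fold, i.e.
ΔpPot = |pPot₁ − pPot₂| ≥ 2.0 on the pKi/pIC50 scale. `samcliff` finds the
most extreme special case: cliffs whose two analogs differ by a **single
atom** (sam_ACs). Two flavors exist:

* **ar_AC (atom replacement)** — one atom's element changes at a fixed
  position, within the four admissible swaps N-C, O-C, N-O, S-O
  (e.g. a pyridine ring nitrogen becomes a benzene CH);
* **aw_AC (atom walk)** — the molecular formula is unchanged and a single
  heteroatom occupies a different position (e.g. a ring nitrogen moves from
  the ortho to the para position relative to a substituent).

Such pairs isolate the potency contribution of one heavy atom and are prime
material for SAR analysis and, when a co-crystallized complex structure
exists, for structure-based rationalization and free-energy methods. The
package is aimed at computational and medicinal chemists who want to mine
ChEMBL-style activity tables for these events.

## What the pipeline does

1. **Curation** (`samcliff.curation`) — keeps only high-confidence records:
   human assay organism, single-protein target, direct-binding assay
   relationship ("D") at confidence score 9, numerically exact (`=`) Ki or
   IC50 values, and a SMILES that standardizes (largest organic fragment,
   neutralized, isotope-free). Values are converted to
   pPot = −log10(molar value); replicates are merged by the arithmetic mean
   of p-values, and groups spanning > 1 log unit are discarded. Ki and IC50
   data are never mixed.
2. **Pair enumeration** (`samcliff.pairs`) — every valence-valid single-atom
   mutant of every compound is indexed by its canonical SMILES. An ar pair
   is a mutant key that equals another compound's own key; an aw pair is two
   compounds sharing a mutant under the same directed swap (provably
   equivalent to the positional-exchange definition). This join is
   near-linear in total atoms and is certified in the test suite against an
   exhaustive brute-force oracle.
3. **Cliff calling** (`samcliff.cliffs`) — target-based pairs (both analogs
   measured on the same target with the same measurement type) become
   sam_ACs when ΔpPot ≥ log10(fold), with the 100-fold boundary inclusive.
4. **X-ray association** (`samcliff.structures`) — targets are mapped to
   UniProt accessions and PDB entries via local tables; an entry is attached
   to a cliff when a co-crystallized ligand is canonically identical to one
   of the analogs (stereo-insensitive by default).
5. **Synthetic benchmarks** (`samcliff.synthetic`) — a deterministic
   generator plants analog series, cliffs, decoys and X-ray tables with
   known ground truth, used throughout the tests.

## Worked example

```bash
samcliff simulate --series 10 --seed 5 --out demo
samcliff run --activities demo/activities.csv \
             --mappings demo/mappings.csv --ligands demo/ligands.csv \
             --out demo_out
```

prints

```
10 series, 30 planted pairs, 9 planted cliffs -> demo
records kept:        60
records excluded:    10
compound potencies:  32
target-based pairs:  30
sam_ACs (cliffs):    9
with X-ray support:  6
```

The fixture plants 10 analog series (30 compounds, 2 ar + 1 aw pair each),
2 inert decoys and 10 deliberately invalid records. Curation keeps the 60
good records and tallies the 10 bad ones; enumeration recovers exactly the
30 planted pairs; 3 of the 10 series were planted as cliff series (9
cliffs), 6 of those cliffs fall on targets with a planted complex
structure. The first data row of `demo_out/sam_acs.csv`,

```
C003_0,C003_1,OCCOCCCc1ccccc1,OCCSCCCc1ccccc1,Ki,4.904...,7.904...,Target 003,
P10003,T003,Enzyme,Lyase,ar_AC,S-O,
```

reads: compounds `C003_0`/`C003_1` differ by one S-O replacement (an ether
oxygen replaced by sulfur), their pKi values differ by 3.0 log units
(1000-fold) on target T003, and no X-ray structure covers this particular
pair (trailing PDB field empty). The weaker analog is always listed first.

The same stages are available as library calls (`standardize`,
`find_replacement_pairs`, `find_walk_pairs`, `call_cliffs`,
`annotate_cliffs`, `run_pipeline`) and as the subcommands `curate`,
`pairs`, `cliffs`, `structures`, `simulate`.

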