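# Methods

This note documents the models and procedures implemented in `abparse`,
their assumptions, the tunable parameters, and what the synthetic test
corpus does and does not establish about behavior on real data.

## Data model and sequence views

A structure entry is a set of polymer *entities* (each with one deposited
sequence, a molecule name and a species) realized as one or more *chains*
per model. Entity metadata comes from the per-entry FASTA file (RCSB header
dialect, with `[auth X]` chain aliases honored); coordinates, experimental
metadata and multi-model organization come from the mmCIF. Waters, ions and
non-polymer ligands are dropped. Models of an ensemble are processed
independently and chains are never paired across models.

Per chain, three sequence views are kept:

* **FASTA-seq** — the entity sequence;
* **PDB-seq** — one-letter codes of residues that have a representative atom
  (Cα for amino acids, C1′ for nucleotides). Nonstandard residues map to
  their tabulated parent (MSE → M), unknowns to X. Residues lacking the
  representative atom are excluded entirely; alternate locations keep the
  highest-occupancy conformer (ties: first altloc code); hydrogens are never
  stored.
* **Filled-seq** — the FASTA-seq fragment from the first to the last aligned
  position of a global PDB-seq→FASTA-seq alignment with free end gaps,
  i.e. the observed span with internal missing residues restored.

Alignment scores: match +2, mismatch −3, gap open −2, gap extend −0.1
(configurable). The PDB-seq is essentially always a true subsequence of the
FASTA-seq, so the scheme deliberately prefers gaps over mismatches; this
makes internal deletions restore correctly and is verified against an
exhaustive alignment oracle on small strings. When alignment identity over
aligned columns drops below 0.8 the Filled-seq falls back to the PDB-seq
with a warning. Optimal alignments are not always unique (repeated
residues); only span-level recovery is guaranteed, which is what downstream
consumers use.

## Antibody chain detection

Detection is a narrow, pluggable contract: sequence in, annotation out
(chain type, variable-domain spans, CDR spans). Adapters for external
annotation tools can be registered; the built-in motif detector is the
default and works from the framework features conserved across
immunoglobulin variable domains:

* first canonical cysteine (framework 1), with ~21 residues before it;
* framework-2 tryptophan 4–24 residues later (closing CDR1);
* second canonical cysteine 55–85 residues after the first;
* J-segment `[FW]G.G` motif 2–40 residues after the second cysteine —
  `WG.G` calls a heavy domain, `FG.G` a light domain.

CDR spans are fixed offsets from these anchors (CDR1 between the first
cysteine and the FR2 tryptophan; CDR3 between the second cysteine and the J
motif; CDR2 by FR2/FR3 offsets). They approximate the classical
numbering-scheme definitions well enough for interface bookkeeping; the
package deliberately does not renumber sequences, and the spans should not
be used as authoritative CDR boundaries.

Two domains at most are called per chain; a chain with one heavy and one
light domain is an HLC (scFv-style construct). Sequences shorter than 70
residues are non-antibody. Both the FASTA-seq and the Filled-seq are
analyzed; the Filled-seq verdict wins because it reflects the resolved
structure (an scFv whose light domain is disordered is, structurally, a
heavy chain), with a flag recording FASTA disagreement. When the FASTA-seq
shows a complete domain but the Filled-seq does not, a guarded
partial-domain scan (floor 30 residues) may still call a truncated domain
from either the CDR3 block (second cysteine with its Y/F context plus the J
motif) or the CDR1 block (N-terminal cysteine, FR2 tryptophan and an FR2
class motif); this is how heavily incomplete chains end up as `VH-`/`VL-`
entries instead of disappearing.

## Structural domain filter

Chains of antibody sequence whose coordinates do not form a variable domain
(light-chain amyloid fibrils are the canonical case) are demoted to
non-antibody by a similarity score against a compact reference domain:

    score = (1/L_ref) · Σ_i 1 / (1 + (d_i/d0)²),
    d0 = max(0.5 Å, 1.24·(L_ref − 15)^⅓ − 1.8)

over a residue correspondence found by gapless threading: every sequence
offset of the query against the reference seeds a least-squares
superposition, each seed is refined by iterating "keep pairs within a
shrinking cap, re-superpose" to a fixed point, and the best-scoring
superposition wins. The score is 1.0 exactly for a rigid copy of the
reference, is bounded by min(1, L_query/L_ref), and is invariant to
rigid-body transforms of the query (machine precision). Gapless
correspondence is a simplification relative to full structural alignment;
it is adequate for the pass/fail use here because folded variable domains
superpose along their whole length and misfolded chains nowhere.

HC-typed chains score against the VH reference, LC-typed against the VL
reference, HLCs against both (either suffices); scores below 0.4
(configurable) demote the chain. The packaged references are *synthetic*
compact Cα folds (spherical-spiral traces carrying the template domain
sequences; filenames marked `_synthetic`); users with high-resolution real
reference domains can point the config at them. The threshold behavior was
validated on fixtures: extended fibril conformations score ≈ 0.06, rigid
copies 1.0.

## Interface geometry

A residue is an interface residue when at least one of its non-hydrogen
atoms lies within 5.0 Å (inclusive; configurable) of any non-hydrogen atom
of the partner chain. Counts are reported summed over both chains, putting a
canonical Fab heavy–light interface in the 40–60 range. Distances run
through a k-d tree and are verified against a brute-force all-pairs oracle
in the tests. The mean interface index (MI) of a chain is the mean of the
1-based ordinals (among residues with coordinates) of its interface
residues — a monotone chain-internal coordinate, unlike author numbering
with its gaps and insertion codes. Chain compactness is the root-mean-square
heavy-atom distance from the heavy-atom centroid. Interfaces are computed on
deposited heavy atoms; a pre-processing hook point exists for users who want
to insert structure-repair tools before geometry, and deviations are
expected to be small for complete crystal structures.

## Heavy–light pairing

Candidates are all (HC,LC), (HC,HLC), (LC,HLC), (HLC,HLC) pairs of one
model, within and between entities; HC–HC and LC–LC are never candidates, so
homodimers (Bence-Jones-type light-chain dimers, VH dimers) decompose into
monomer entries. A candidate survives when its interface count meets the
per-combination minimum: 20 for HC–LC (and the HLC mixed combinations), 80
for HLC–HLC — two tethered VH–VL chains must bury roughly two Fv interfaces
to count as a genuine pair rather than a crystal contact.

Pair score: `3·N_interface − floor((MI_H + MI_L)/2)`; a dummy pair (unpaired
chain) scores −100. The −100 constant makes any pair with a modest genuine
interface and variable-domain contacts beat leaving two chains single, while
a constant-domain contact (MI ≈ 200) scores below a dummy and is never
forced. The reward scale 3 balances typical interface sizes (20–80) against
index penalties (20–200).

Optimization is greedy construction plus local search. Greedy: give every
chain a dummy placeholder, rank all pairs (real and dummy) by score with
lexicographic tie-breaks, select top-down subject to each chain used once.
Refinement: repeatedly force one unused candidate into the solution, remove
conflicting selected pairs, greedily re-complete the remainder from the
pool (displaced chains fall back to dummies), and accept the move only when
the total strictly increases; substituted pairs return to the pool. The
total is strictly increasing and bounded, so termination is guaranteed. The
re-completion step is what lets a single move express two-pair swaps; on
200 random instances of up to 8 chains the refined total matches an
exhaustive matching oracle ≥ 95 % of the time (typically 97–99 %) and never
drops below the greedy total. The exhaustive oracle (≤ 10 chains) breaks
score ties by the lexicographically smallest sorted tuple of real pairs, so
an all-dummy solution wins a tie against any real pairing; every run is
bit-reproducible.

## Chain-type classification

A pure function of Filled-seq length, pairing context, entity annotations
and mean radius. Length windows (configurable, chosen from the ~110 aa
single-domain and ~220 aa Fab-arm norms): single domain 95–150, Fab arm
190–260, two-domain single chain 190–290. Within the Fab window an HC/LC is
`FabH`/`FabL`; within the single-domain window `VH`/`VHH`/`VL`; below a
window the `-` variant (incomplete domain); anything longer that is not a
Fab arm gets `+` (extra domains, fusions — deliberately broad). An unpaired
single heavy domain is a `VHH` when the species is on the camelid/shark
list, the molecule name carries a nanobody keyword, or the framework-2
segment matches the hydrophilic hallmark regex (default `.{7}ER` on the 12
residues after the FR2 tryptophan — the positions that face the VL in a
conventional VH); paired heavy domains are never VHH. HLCs are `scFv` when
the molecule name contains an scFv-style keyword (checked case-insensitively;
`scFv` itself contains `Fv`) AND mean radius ≤ 20 Å, else `VHVL`; the
radius cutoff separates tethered, packed VH–VL from loose fusions and was
validated on fixture constructs built tight (≤ 18 Å) and loose (≥ 24 Å).
Paired entries render as `heavy:light` (e.g. `FabH:FabL`, `VH-:VL`),
unpaired as the single component.

## Antigen identification

For each antibody (pair or single chain), every other polymer chain of the
model is screened — including antibody chains of *other* entries, so
anti-idiotype complexes are representable; the antibody's own chains are
not candidates. Acceptance needs all three (inclusive): total interface
≥ 10 residues; ≥ 5 antibody-side interface residues inside CDR spans
(mapped from Filled-seq coordinates through the residue index map, so
missing residues drop out correctly); CDR fraction of the antibody-side
interface ≥ 0.25. Nucleic-acid candidates use nucleotides with C1′
representative atoms and the same thresholds; carbohydrates and haptens are
out of scope. Accepted antigens are merged into one record per antibody
with statistics recomputed against the union; screening order does not
affect the result.

## Affinity data

The curated table is tab-separated (pdb_id, chain keys, K_D in nM, method,
temperature, reference) and maintained independently of structure parsing.
Aggregation per interaction: ITC records, if any, exclude all others;
otherwise the most frequent method wins (ties alphabetically, aggregate
flagged as mixed). Within the chosen set the geometric mean combines
values — K_D spans many orders of magnitude, and the geometric mean is the
arithmetic mean in pK_D space (pK_D = 9 − log10 K_D[nM]). "Room
temperature" normalizes to 298 K; non-unanimous temperatures become "N.A.";
non-positive K_D rows are rejected with a warning.

## Summary database

One row per antibody entry per model, 43 registered columns (antibody
block, antigen block, entry metadata, affinity); the column registry is
versioned in the file header and changing it requires a version bump. For a
single-chain VH–VL construct the chain occupies the heavy block and its
light-domain CDRs fill the L-CDR columns. Missing text fields are "N.A.",
missing numeric fields 0. Default multi-model policy is first model only
(the model count is recorded); `--all-models` emits one row set per model.
Rows order deterministically by (pdb id, model, heavy chain, light chain).
Updates are checksum-driven (SHA-256 over both input files, kept in a JSON
manifest beside the summary): unchanged entries are carried over
byte-identically, removed entries drop out, changed/new entries are
recomputed, and a failing entry keeps its old rows and is reported without
aborting. Incremental update and full rebuild of the same inputs are
byte-identical.

## Synthetic fixtures

The generator builds mmCIF+FASTA pairs with exact ground truth. Chains are
spherical-spiral Cα traces in home regions 1000 Å apart; antibody chains
embed the reference-domain geometry for their variable domain (so they pass
the structural filter by construction); designed contacts are realized as
pseudo side-chain atoms in isolated meeting regions so that exactly the
designated residue sets fall within the cutoff — realized counts and mean
indices are re-verified post generation. Missing-residue masks delete
coordinates but not FASTA letters. Sequences embed the framework anchors of
the built-in detector; filler comes from an anchor-free alphabet. Same seed,
same bytes.

These fixtures are geometric idealizations. Passing tests establish that
the *computations* — interface counting, score arithmetic, optimization,
window/radius classification, screening thresholds, database mechanics —
are correct on inputs whose ground truth is known exactly. They do not
establish detector accuracy on divergent natural repertoires (the motif
detector is anchor-based, not a learned or numbering-based annotator), nor
interface statistics on structures needing repair (missing side chains
reduce counts slightly), nor classification of exotic engineered formats
beyond the implemented label vocabulary. The two showcase complexes
reproduce the *score structure* of real multi-Fab entries in which raw
contact counts favor swapped pairings; on such real entries the same
penalty mechanism selects the deposited (true) pairings.

## Numerical choices and degenerate inputs

* Distance cutoffs are inclusive (≤), pinned in config so counts are stable.
* The mean-index penalty uses `floor`, keeping scores integer.
* All tie-breaks (pair ranking, brute-force solutions, altloc selection)
  are lexicographic, making every pipeline stage deterministic.
* Chains with zero representative atoms are excluded at parse time with a
  warning; an interface query against an atom-free candidate returns a
  reasoned rejection; a reference domain shorter than 16 residues is an
  error (the d0 formula is undefined there).
* Problem sizes in the test suite and the acceptance script (two- and
  four-Fab showcases, 200 optimizer instances of ≤ 8 chains, 100
  random-cloud interface fixtures) were chosen so every quantity is
  recomputed from scratch in seconds while still covering the combinatorial
  space where greedy pairing alone fails.

## Known limitations

* The built-in detector requires the canonical anchors (or, for truncated
  chains, the guarded partial patterns); heavily engineered frameworks may
  need an external detector adapter.
* V-gene subgroup assignment is a placeholder column (an external-tool
  adapter may fill it; no built-in fallback is provided, since it requires
  germline reference databases).
* No structure repair: entries deposited as Cα-only traces will under-count
  interfaces unless repaired upstream via the pre-processing hook.
* Assemblies/biounit expansion, legacy PDB format, and carbohydrate/hapten
  antigens are out of scope.
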