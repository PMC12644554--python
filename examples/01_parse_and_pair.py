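"""Parse a multi-Fab complex and pair its heavy and light chains.

Builds a synthetic two-Fab entry in which raw contact counts favor the
*wrong* (swapped) heavy-light assignment, runs the full workflow, and shows
how the mean-interface-index penalty recovers the designed pairing.
"""

from tempfile import TemporaryDirectory

from abparse.fixtures import SHOWCASE_SMALL_COUNTS, pairing_showcase_small, write_fixture
from abparse.interface_geometry import interface_residues
from abparse.pipeline import process_entry
from abparse.structure_io import parse_entry

with TemporaryDirectory() as tmp:
    cif_path, fasta_path, truth = write_fixture(pairing_showcase_small(), tmp)

    _, models, meta = parse_entry(cif_path, fasta_path)
    chains = {c.chain_id: c for c in models[1]}
    print(f"entry {meta.pdb_id}: chains {sorted(chains)} (heavy: A,H; light: B,L)")
    print("\ninterface residue counts at 5 Å (summed over both chains):")
    for (h, l), designed in sorted(SHOWCASE_SMALL_COUNTS.items()):
        r = interface_residues(chains[h], chains[l])
        print(f"  {h}-{l}: {r.n_total:3d}   mean interface indices "
              f"{r.mean_index_a:6.1f} / {r.mean_index_b:6.1f}")

    result = process_entry(cif_path, fasta_path)
    solution = result.models[0].solution
    print("\nselected pairing:", sorted(solution.real_pairs()),
          f"(total score {solution.total_score})")
    for entry in result.models[0].entries:
        print(f"  {entry.key[0]}:{entry.key[1]} -> {entry.type_call.label}, "
              f"{entry.n_hl_interface} interface residues")

print(
    "\nThe cross pairs A-L and H-B bury MORE residues (50/52 vs 44/48), but "
    "their contacts sit at high residue indices (constant domains), so the "
    "mean-index penalty makes A-B and H-L win: contact counts alone would "
    "pair the chains incorrectly."
)
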