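"""Entity/chain parsing, PDB-seq extraction and Filled-seq construction."""

import warnings

import pytest

from abparse.config import AlignmentConfig
from abparse.fixtures import ChainSpec, FixtureSpec, write_fixture
from abparse.structure_io import (
    EntityRecord,
    build_filled_seq,
    one_letter,
    parse_entry,
    read_entry_fasta,
)


def exhaustive_best_alignment(pdb_seq, fasta_seq, cfg):
    """Brute-force alignment oracle for tiny strings: enumerate every
    monotone mapping of pdb positions onto fasta positions and score it with
    the configured scheme (free end gaps)."""
    from itertools import combinations

    best = None
    n, m = len(pdb_seq), len(fasta_seq)
    for positions in combinations(range(m), n):
        score = 0.0
        for i, p in enumerate(positions):
            score += cfg.match if pdb_seq[i] == fasta_seq[p] else cfg.mismatch
        # internal gaps in the fasta between consecutive aligned columns
        for a, b in zip(positions, positions[1:]):
            gap = b - a - 1
            if gap:
                score += cfg.gap_open + cfg.gap_extend * (gap - 1)
        if best is None or score > best[0]:
            best = (score, positions)
    return best


class TestFastaParsing:
    def test_rcsb_dialect_with_auth_chain_ids(self, tmp_path):
        text = (
            ">8XYZ_1|Chains A[auth H], B[auth L]|immunoglobulin|Homo sapiens\n"
            "EVQLVESGG\n"
            ">8XYZ_2|Chain C|lysozyme|Gallus gallus\nKVFGRCELA\n"
        )
        p = tmp_path / "e.fasta"
        p.write_text(text)
        pdb_id, records = read_entry_fasta(p)
        assert pdb_id == "8xyz"
        assert records[0].chain_ids == ["H", "L"]
        assert records[0].species == "Homo sapiens"
        assert records[1].chain_ids == ["C"]
        assert records[1].molecule_name == "lysozyme"

    def test_entity_invariants(self):
        with pytest.raises(ValueError):
            EntityRecord(entity_id="1", sequence="", chain_ids=["A"])
        with pytest.raises(ValueError):
            EntityRecord(entity_id="1", sequence="AG", chain_ids=["A", "A"])


class TestParseEntry:
    def test_single_model_two_chains(self, showcase_small):
        cif, fasta, _ = showcase_small
        entities, models, meta = parse_entry(cif, fasta)
        assert list(models) == [1]
        assert {c.chain_id for c in models[1]} == {"A", "B", "H", "L"}
        assert all(c.model_id == 1 for c in models[1])

    def test_nmr_ensemble_yields_separate_models(self, tmp_path):
        spec = FixtureSpec(
            pdb_id="nmr1",
            chains=[ChainSpec("A", "HC", length=110)],
            n_models=10,
        )
        cif, fasta, _ = write_fixture(spec, tmp_path)
        _, models, meta = parse_entry(cif, fasta)
        assert sorted(models) == list(range(1, 11))
        assert meta.n_models == 10
        for mid, chains in models.items():
            assert all(c.model_id == mid for c in chains)

    def test_water_chain_dropped(self, tmp_path):
        spec = FixtureSpec(
            pdb_id="wat1",
            chains=[ChainSpec("A", "antigen", length=80)],
            include_water=True,
        )
        cif, fasta, _ = write_fixture(spec, tmp_path)
        _, models, _ = parse_entry(cif, fasta)
        assert [c.chain_id for c in models[1]] == ["A"]

    def test_fixtures_parse_without_warnings(self, showcase_small, showcase_large):
        for cif, fasta, _ in (showcase_small, showcase_large):
            with warnings.catch_warnings():
                warnings.simplefilter("error")
                parse_entry(cif, fasta)

    def test_sequence_length_ordering_invariant(self, tmp_path):
        spec = FixtureSpec(
            pdb_id="mask1",
            chains=[ChainSpec("A", "HC", length=140, missing=(1, 2, 50, 51, 52, 140))],
        )
        cif, fasta, _ = write_fixture(spec, tmp_path)
        entities, models, _ = parse_entry(cif, fasta)
        chain = models[1][0]
        fasta_len = len(entities[0].sequence)
        assert len(chain.pdb_seq) <= len(chain.filled_seq) <= fasta_len
        assert len(chain.pdb_seq) == 140 - 6
        # internal deletions restored, leading/trailing ones not
        assert chain.filled_seq == entities[0].sequence[2:139]
        # every mapped residue keeps its letter and the map is monotone
        aligned = [p for p in chain.map_pdb_to_fasta if p is not None]
        assert all(b > a for a, b in zip(aligned, aligned[1:]))
        assert all(
            entities[0].sequence[p - 1] == chain.pdb_seq[i]
            for i, p in enumerate(chain.map_pdb_to_fasta)
            if p is not None
        )


class TestOneLetter:
    @pytest.mark.parametrize(
        "name,code",
        [("ALA", "A"), ("GLY", "G"), ("MSE", "M"), ("UNK", "X"), ("XYZQ", "X")],
    )
    def test_standard_and_nonstandard_mapping(self, name, code):
        assert one_letter(name) == code


class TestFilledSeq:
    def test_internal_gap_restored(self):
        filled, index_map, start = build_filled_seq("CDFG", "ABCDEFGH")
        assert filled == "CDEFG"
        assert index_map == [3, 4, 6, 7]
        assert start == 3

    def test_identity_case(self):
        seq = "MKTAYIAKQR"
        filled, index_map, start = build_filled_seq(seq, seq)
        assert filled == seq
        assert index_map == list(range(1, len(seq) + 1))
        assert start == 1

    def test_gap_preferred_over_mismatch_matches_exhaustive_oracle(self):
        # oracle (recomputed here) prefers aligning G to G across a 3-gap:
        # score 2+2-(2+0.1+0.1)=1.8 beats the mismatch alignment 2-3=-1
        cfg = AlignmentConfig()
        score, positions = exhaustive_best_alignment("AG", "AXXXG", cfg)
        assert positions == (0, 4)
        filled, index_map, _ = build_filled_seq("AG", "AXXXG", cfg)
        assert filled == "AXXXG"
        assert index_map == [1, 5]

    def test_low_identity_falls_back_to_pdb_seq(self):
        with pytest.warns(UserWarning, match="identity"):
            filled, index_map, _ = build_filled_seq("WWWWYYYY", "AAAAGGGG")
        assert filled == "WWWWYYYY"
        assert index_map is None

    @pytest.mark.parametrize(
        "mask",
        [
            (1, 2, 3),                      # disordered N-terminus
            (60, 61, 62, 63),               # internal loop
            (25, 26, 95, 96, 97, 130),      # several gaps
            (139, 140),                     # disordered C-terminus
        ],
    )
    def test_designed_deletion_masks_recovered_exactly(self, mask):
        # antibody-like sequence (variable domain + unique filler) where the
        # designed alignment is the unique optimum
        import numpy as np

        from abparse.fixtures import VH_TEMPLATE, filler

        fasta = VH_TEMPLATE + filler(30, np.random.default_rng(5))
        keep = [p for p in range(1, len(fasta) + 1) if p not in mask]
        pdb = "".join(fasta[p - 1] for p in keep)
        filled, index_map, start = build_filled_seq(pdb, fasta)
        assert index_map == keep
        assert filled == fasta[keep[0] - 1 : keep[-1]]
        assert start == keep[0]

    def test_alignment_score_matches_exhaustive_oracle_on_tiny_strings(self):
        import numpy as np
        from Bio import Align

        from abparse.structure_io import _make_aligner

        cfg = AlignmentConfig()
        aligner = _make_aligner(cfg)
        rng = np.random.default_rng(11)
        alphabet = "ACDEFG"
        for _ in range(40):
            m = int(rng.integers(4, 10))
            fasta = "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=m))
            keep = sorted(rng.choice(m, size=int(rng.integers(2, m)), replace=False))
            pdb = "".join(fasta[i] for i in keep)
            oracle_score, _ = exhaustive_best_alignment(pdb, fasta, cfg)
            assert aligner.score(fasta, pdb) == pytest.approx(oracle_score)

    def test_index_map_monotone_and_letter_preserving_on_random_sequences(self):
        import numpy as np

        rng = np.random.default_rng(7)
        alphabet = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(30):
            n = int(rng.integers(30, 120))
            fasta = "".join(alphabet[i] for i in rng.integers(0, 20, size=n))
            keep = sorted(rng.choice(n, size=int(rng.integers(10, n)), replace=False))
            pdb = "".join(fasta[i] for i in keep)
            filled, index_map, _ = build_filled_seq(pdb, fasta)
            aligned = [p for p in index_map if p is not None]
            assert all(b > a for a, b in zip(aligned, aligned[1:]))
            assert filled == fasta[aligned[0] - 1 : aligned[-1]]
            assert len(pdb) <= len(filled) <= len(fasta)
            # an optimal alignment of a true subsequence may trade a rare
            # mismatch against gap openings; most columns still match
            mismatches = sum(
                1
                for i, p in enumerate(index_map)
                if p is not None and fasta[p - 1] != pdb[i]
            )
            assert mismatches <= max(1, len(pdb) // 10)
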