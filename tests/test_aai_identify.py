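"""Antigen screening criteria and interaction grouping."""

import numpy as np
import pytest

from abparse.aai_identify import cdr_seq_indices, group_antigens, screen_antigen
from abparse.ab_detect import AbAnnotation, detect_ab
from abparse.fixtures import (
    ChainSpec,
    ContactSpec,
    FixtureSpec,
    write_fixture,
)
from abparse.pipeline import process_entry
from abparse.structure_io import parse_entry


def chain_with_contacts(point_chain_factory, chain_id, n_res, contact_idx, partner_xyz):
    """Chain of n_res residues at y=0; residues in contact_idx get an extra
    atom near partner_xyz[i]."""
    pts = []
    k = 0
    for i in range(1, n_res + 1):
        base = [(50.0 * i, 0.0, 0.0)]
        if i in contact_idx:
            base.append(tuple(np.asarray(partner_xyz[k]) + (0.0, 3.0, 0.0)))
            k += 1
        pts.append(base)
    return point_chain_factory(pts, chain_id=chain_id)


class TestScreenAntigen:
    def make_pair(self, point_chain_factory, n_ab_contacts, n_cdr, n_ag_contacts):
        """Antibody chain (40 residues, CDR = 1..10) + candidate antigen with a
        designed interface: n_ab_contacts antibody residues of which n_cdr in
        the CDR region, against n_ag_contacts antigen residues."""
        # one slot per antigen contact residue; antibody contact atoms cycle
        # over those slots so every designated residue is within the cutoff
        slots = [(10.0 * k, 1000.0, 500.0) for k in range(n_ag_contacts)]
        ab_idx = list(range(1, n_cdr + 1)) + list(range(15, 15 + (n_ab_contacts - n_cdr)))
        ab = chain_with_contacts(
            point_chain_factory, "H", 40, set(ab_idx),
            [slots[k % len(slots)] for k in range(n_ab_contacts)],
        )
        ag_idx = set(range(1, n_ag_contacts + 1))
        ag_pts = []
        for i in range(1, 41):
            base = [(50.0 * i, 500.0, 0.0)]
            if i in ag_idx:
                base.append(slots[i - 1])
            ag_pts.append(base)
        ag = point_chain_factory(ag_pts, chain_id="G")
        ann = AbAnnotation("HC", vh_span=(1, 40), cdr_spans=[("H1", (1, 10))])
        return [(ab, ann)], ag

    def test_acceptance_at_exact_boundaries(self, point_chain_factory):
        # 5 ab-side residues (5 CDR) + 5 antigen residues = 10 total, ratio 1.0
        ab_side, ag = self.make_pair(point_chain_factory, 5, 5, 5)
        res = screen_antigen(ab_side, ag)
        assert (res.n_interface, res.n_cdr_interface) == (10, 5)
        assert res.accepted

    def test_interface_below_ten_rejected(self, point_chain_factory):
        ab_side, ag = self.make_pair(point_chain_factory, 5, 5, 4)  # 9 total
        res = screen_antigen(ab_side, ag)
        assert res.n_interface == 9
        assert not res.accepted

    def test_low_cdr_ratio_rejected(self, point_chain_factory):
        # 25 ab-side residues, 5 CDR -> ratio 0.2 < 0.25
        ab_side, ag = self.make_pair(point_chain_factory, 25, 5, 15)
        res = screen_antigen(ab_side, ag)
        assert res.n_cdr_interface == 5
        assert res.cdr_ratio == pytest.approx(0.2)
        assert not res.accepted

    def test_ratio_boundary_inclusive(self, point_chain_factory):
        # 20 ab-side, 5 CDR -> ratio exactly 0.25
        ab_side, ag = self.make_pair(point_chain_factory, 20, 5, 10)
        res = screen_antigen(ab_side, ag)
        assert res.cdr_ratio == pytest.approx(0.25)
        assert res.accepted

    def test_candidate_without_atoms_rejected_with_reason(self, point_chain_factory):
        ab_side, _ = self.make_pair(point_chain_factory, 5, 5, 5)
        from abparse.structure_io import ChainStructure, Residue

        empty = ChainStructure(
            chain_id="Z", model_id=1, entity_id="",
            residues=[Residue("ALA", 1, 1, "", [])],
        )
        res = screen_antigen(ab_side, empty)
        assert not res.accepted and "heavy atoms" in res.reason


class TestCdrMapping:
    def test_spans_map_through_missing_residues(self, tmp_path):
        # CDR-H2 is 50..63 on the Filled-seq; residues 55-58 are unresolved,
        # so their seq_index values must vanish from the structure-side set
        spec = FixtureSpec(
            pdb_id="map2",
            chains=[ChainSpec("A", "HC", length=110, missing=(55, 56, 57, 58))],
        )
        cif, fasta, _ = write_fixture(spec, tmp_path)
        _, models, _ = parse_entry(cif, fasta)
        chain = models[1][0]
        ann = detect_ab(chain.filled_seq)
        idx = cdr_seq_indices(chain, ann)
        # positions 1..54 keep their index; >=59 shift down by 4
        expected = set(range(26, 35)) | set(range(50, 55)) | set(range(59 - 4, 64 - 4))
        expected |= {i - 4 for i in range(95, 103)}
        assert idx == expected


class TestGrouping:
    def _entry(self, tmp_path, contacts, extra_chains=()):
        spec = FixtureSpec(
            pdb_id="grp1", seed=1,
            chains=[
                ChainSpec("H", "HC", length=110),
                *extra_chains,
            ],
            contacts=contacts,
        )
        return write_fixture(spec, tmp_path)

    def test_two_chain_antigen_grouped_into_one_record(self, tmp_path):
        cif, fasta, _ = self._entry(
            tmp_path,
            contacts=[
                ContactSpec("H", "G", (26, 27, 28, 29, 30), (1, 2, 3, 4, 5)),
                ContactSpec("H", "F", (95, 96, 97, 98, 99), (7, 8, 9, 10, 11)),
            ],
            extra_chains=(
                ChainSpec("G", "antigen", length=80),
                ChainSpec("F", "antigen", length=80),
            ),
        )
        result = process_entry(cif, fasta)
        entry = result.models[0].entries[0]
        assert entry.aai is not None
        assert [c.chain_id for c in entry.aai.antigen_chains] == ["F", "G"]
        # union statistics: 10 ab-side + 10 ag-side residues
        assert entry.aai.n_interface == 20
        assert entry.aai.n_cdr_interface == 10
        assert entry.aai.cdr_ratio == pytest.approx(1.0)

    def test_no_contact_yields_ab_only_entry(self, tmp_path):
        cif, fasta, _ = self._entry(
            tmp_path, contacts=[], extra_chains=(ChainSpec("G", "antigen", length=80),)
        )
        result = process_entry(cif, fasta)
        entry = result.models[0].entries[0]
        assert entry.aai is None

    def test_lattice_contact_without_cdr_excluded(self, tmp_path):
        # 12 interface residues but only 2 in CDRs: criterion 2 fails
        cif, fasta, _ = self._entry(
            tmp_path,
            contacts=[ContactSpec("H", "G", (26, 27, 70, 71, 72, 73), (1, 2, 3, 4, 5, 6))],
            extra_chains=(ChainSpec("G", "antigen", length=80),),
        )
        result = process_entry(cif, fasta)
        assert result.models[0].entries[0].aai is None

    def test_grouping_invariant_under_candidate_order(self, point_chain_factory):
        rng = np.random.default_rng(5)
        screen = TestScreenAntigen()
        ab_side, ag1 = screen.make_pair(point_chain_factory, 5, 5, 5)
        _, ag2 = screen.make_pair(point_chain_factory, 5, 5, 6)
        ag2.chain_id = "Z"
        rec_fwd = group_antigens("H", None, ab_side, [ag1, ag2])
        rec_rev = group_antigens("H", None, ab_side, [ag2, ag1])
        assert [c.chain_id for c in rec_fwd.antigen_chains] == [
            c.chain_id for c in rec_rev.antigen_chains
        ]
        assert rec_fwd.n_interface == rec_rev.n_interface

    def test_record_invariants(self, tmp_path):
        cif, fasta, _ = self._entry(
            tmp_path,
            contacts=[ContactSpec("H", "G", (26, 27, 28, 50, 51, 95), (1, 2, 3, 4, 5, 6))],
            extra_chains=(ChainSpec("G", "antigen", length=80),),
        )
        result = process_entry(cif, fasta)
        aai = result.models[0].entries[0].aai
        assert aai is not None
        ab_side_count = aai.n_interface - 6  # 6 designed antigen-side residues
        assert aai.n_cdr_interface <= ab_side_count
        assert 0.25 <= aai.cdr_ratio <= 1.0


class TestNucleicAntigens:
    def test_dna_chain_accepted_with_same_thresholds(self, tmp_path):
        spec = FixtureSpec(
            pdb_id="nuc1", seed=2,
            chains=[
                ChainSpec("H", "HC", length=110),
                ChainSpec("D", "antigen", length=30, polymer="dna"),
            ],
            contacts=[
                ContactSpec("H", "D", (26, 27, 28, 95, 96), (1, 2, 3, 4, 5)),
            ],
        )
        cif, fasta, _ = write_fixture(spec, tmp_path)
        result = process_entry(cif, fasta)
        entry = result.models[0].entries[0]
        assert entry.aai is not None
        assert entry.aai.antigen_chains[0].polymer_kind == "dna"
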