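"""Summary rows, file round-trips and incremental database updates."""

import pytest

from abparse.affinity import AffinityRecord, affinity_index
from abparse.config import Config
from abparse.fixtures import (
    ChainSpec,
    ContactSpec,
    FixtureSpec,
    pairing_showcase_small,
    write_fixture,
)
from abparse.pipeline import process_entry
from abparse.summary_db import (
    COLUMNS,
    build_database,
    build_entry,
    read_summary,
    update_database,
    write_summary,
)


@pytest.fixture(scope="module")
def corpus(tmp_path_factory):
    """Three-entry input directory: a two-Fab complex, a VHH + antigen
    interaction, and an apo single-domain entry."""
    d = tmp_path_factory.mktemp("corpus")
    write_fixture(pairing_showcase_small(), d)
    write_fixture(
        FixtureSpec(
            pdb_id="vhh1", seed=4,
            chains=[
                ChainSpec("N", "HC", length=110, vhh=True, species="Lama glama",
                          molecule_name="nanobody"),
                ChainSpec("G", "antigen", length=90, molecule_name="toxin"),
            ],
            contacts=[ContactSpec("N", "G", (26, 27, 28, 95, 96, 97), (1, 2, 3, 4, 5, 6))],
        ),
        d,
    )
    write_fixture(
        FixtureSpec(
            pdb_id="apo1", seed=5,
            chains=[ChainSpec("A", "HC", length=110, vhh=True, species="Vicugna pacos")],
        ),
        d,
    )
    return d


class TestBuildEntry:
    def test_fab_with_antigen_row(self, corpus):
        result = process_entry(corpus / "vhh1.cif", corpus / "vhh1.fasta")
        rows = build_entry(result)
        assert len(rows) == 1
        v = rows[0].values
        assert v["ab_type"] == "VHH"
        assert v["ag_chain_ids"] == "G"
        assert v["l_chain_id"] == "N.A."
        assert v["l_fasta_len"] == "0"
        assert int(v["n_ab_ag_interface"]) == 12
        assert v["h_species"] == "Lama glama"

    def test_apo_entry_has_na_or_zero_antigen_fields(self, corpus):
        result = process_entry(corpus / "apo1.cif", corpus / "apo1.fasta")
        rows = build_entry(result)
        v = rows[0].values
        assert v["ag_chain_ids"] == "N.A."
        assert v["n_ab_ag_interface"] == "0"
        assert v["cdr_ratio"] == "0"
        assert v["kd_nM"] == "0"

    def test_row_has_all_registry_columns(self, corpus):
        result = process_entry(corpus / "apo1.cif", corpus / "apo1.fasta")
        row = build_entry(result)[0]
        assert set(row.values) == set(COLUMNS)
        assert len(COLUMNS) == 43

    def test_affinity_merged_by_chain_key(self, corpus):
        result = process_entry(corpus / "vhh1.cif", corpus / "vhh1.fasta")
        idx = affinity_index(
            [AffinityRecord("vhh1", "N", "N.A.", "G", 12.0, "ITC", "298")]
        )
        v = build_entry(result, idx)[0].values
        assert v["affinity_method"] == "ITC"
        assert float(v["kd_nM"]) == pytest.approx(12.0)
        assert float(v["pkd"]) == pytest.approx(9.0 - 1.0791812, abs=1e-3)

    def test_multimodel_default_first_model_only(self, tmp_path):
        spec = FixtureSpec(
            pdb_id="nmr2", chains=[ChainSpec("A", "HC", length=110)], n_models=5
        )
        cif, fasta, _ = write_fixture(spec, tmp_path)
        rows = build_entry(process_entry(cif, fasta))
        assert len(rows) == 1 and rows[0].values["model_id"] == "1"
        cfg = Config()
        cfg.summary.all_models = True
        rows = build_entry(process_entry(cif, fasta, cfg), config=cfg)
        assert [r.values["model_id"] for r in rows] == ["1", "2", "3", "4", "5"]


class TestStructureExport:
    def test_processed_mmcif_written_per_antibody_entry(self, corpus, tmp_path):
        import gemmi

        from abparse.summary_db import write_antibody_structures

        result = process_entry(corpus / "fab2.cif", corpus / "fab2.fasta")
        paths = write_antibody_structures(result, tmp_path / "structs")
        assert [p.name for p in paths] == ["fab2_m1_A_B.cif", "fab2_m1_H_L.cif"]
        st = gemmi.read_structure(str(paths[0]))
        assert sorted(ch.name for ch in st[0]) == ["A", "B"]


class TestSubgroupAdapter:
    def test_external_adapter_fills_column_hlc_excluded(self, corpus):
        import abparse.ab_detect as det

        det.register_subgroup_adapter(lambda seq, ct: f"{ct}-subgroup-1")
        try:
            assert det.assign_subgroup("X", "HC") == "HC-subgroup-1"
            assert det.assign_subgroup("X", "HLC") == "N.A."
            result = process_entry(corpus / "vhh1.cif", corpus / "vhh1.fasta")
            v = build_entry(result)[0].values
            assert v["h_subgroup"] == "HC-subgroup-1"
        finally:
            det._SUBGROUP_ADAPTER = None
        result = process_entry(corpus / "vhh1.cif", corpus / "vhh1.fasta")
        assert build_entry(result)[0].values["h_subgroup"] == "N.A."


class TestSummaryIO:
    def test_round_trip(self, corpus, tmp_path):
        result = process_entry(corpus / "fab2.cif", corpus / "fab2.fasta")
        rows = build_entry(result)
        path = tmp_path / "summary.tsv"
        write_summary(path, rows)
        back = read_summary(path)
        assert [r.values for r in back] == [r.values for r in rows]

    def test_rejects_foreign_files(self, tmp_path):
        p = tmp_path / "x.tsv"
        p.write_text("pdb_id\tstuff\n")
        with pytest.raises(ValueError):
            read_summary(p)


class TestUpdate:
    def test_empty_change_set_is_byte_identical(self, corpus, tmp_path):
        summary = tmp_path / "db.tsv"
        build_database(corpus, summary)
        before = summary.read_bytes()
        report = update_database(summary, corpus)
        assert report.processed == []
        assert len(report.skipped_unchanged) == 3
        assert summary.read_bytes() == before

    def test_touched_but_identical_content_short_circuits(self, corpus, tmp_path):
        import os
        import shutil

        workdir = tmp_path / "in"
        shutil.copytree(corpus, workdir)
        summary = tmp_path / "db.tsv"
        build_database(workdir, summary)
        before = summary.read_bytes()
        os.utime(workdir / "apo1.cif")  # touch without content change
        report = update_database(summary, workdir)
        assert report.processed == []  # checksum short-circuit
        assert summary.read_bytes() == before

    def test_removed_entry_rows_disappear(self, corpus, tmp_path):
        import shutil

        workdir = tmp_path / "in"
        shutil.copytree(corpus, workdir)
        summary = tmp_path / "db.tsv"
        build_database(workdir, summary)
        (workdir / "vhh1.cif").unlink()
        (workdir / "vhh1.fasta").unlink()
        report = update_database(summary, workdir)
        assert report.removed == ["vhh1"]
        assert all(r.values["pdb_id"] != "vhh1" for r in read_summary(summary))

    def test_incremental_equals_full_rebuild(self, corpus, tmp_path):
        import shutil

        workdir = tmp_path / "in"
        shutil.copytree(corpus, workdir)
        summary = tmp_path / "db.tsv"
        build_database(workdir, summary)

        # add one entry and modify another
        write_fixture(
            FixtureSpec(
                pdb_id="new1", seed=9,
                chains=[ChainSpec("A", "HC", length=110)],
            ),
            workdir,
        )
        write_fixture(
            FixtureSpec(
                pdb_id="apo1", seed=6,  # different seed: new filler sequence
                chains=[ChainSpec("A", "HC", length=110, vhh=True,
                                  species="Vicugna pacos")],
            ),
            workdir,
        )
        update_database(summary, workdir)
        incremental = summary.read_bytes()

        fresh = tmp_path / "fresh.tsv"
        build_database(workdir, fresh)
        assert incremental == fresh.read_bytes()

    def test_failing_entry_keeps_old_rows_and_is_reported(self, corpus, tmp_path):
        import shutil

        workdir = tmp_path / "in"
        shutil.copytree(corpus, workdir)
        summary = tmp_path / "db.tsv"
        build_database(workdir, summary)
        n_before = len([r for r in read_summary(summary) if r.values["pdb_id"] == "apo1"])
        (workdir / "apo1.cif").write_text("this is not an mmCIF file")
        report = update_database(summary, workdir)
        assert "apo1" in report.errors
        kept = [r for r in read_summary(summary) if r.values["pdb_id"] == "apo1"]
        assert len(kept) == n_before
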