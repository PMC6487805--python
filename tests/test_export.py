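import zipfile

import pytest

from lampmask.classify import classify_alignment
from lampmask.errors import (
    OutputCollisionError,
    RegionSizeError,
    UnknownGroupError,
)
from lampmask.export import (
    build_focal_consensus,
    bundle_outputs,
    make_masked_target,
    make_primerexplorer_input,
    read_masked_target,
    write_masked_target,
)
from lampmask.synth import PlantPlan, generate_alignment


class TestFocalConsensus:
    def test_single_strain_is_its_degapped_subsequence(self):
        aln, _ = generate_alignment(
            PlantPlan(
                n_groups=2,
                strains_per_group=[1, 2],
                n_columns=40,
                gap_blocks={"G1": [(10, 12)]},
                seed=5,
            )
        )
        seq, cmap = build_focal_consensus(aln, "G1", (1, 40))
        rec = aln.members("G1")[0]
        assert seq == rec.sequence.replace("-", "")
        assert all(c < 10 or c > 12 for c in cmap)
        assert cmap == sorted(cmap)

    def test_majority_base_wins(self):
        aln, _ = generate_alignment(
            PlantPlan(n_groups=2, strains_per_group=3, n_columns=30, seed=5)
        )
        # rebuild one G1 strain to disagree at column 10
        from lampmask.alignment import GroupedAlignment, StrainRecord

        recs = list(aln.records)
        r = recs[0]
        backbone_base = r.sequence[9]
        alt = "A" if backbone_base != "A" else "C"
        recs[0] = StrainRecord(
            taxon_id=r.taxon_id,
            strain_id=r.strain_id,
            gene_id=r.gene_id,
            sequence=r.sequence[:9] + alt + r.sequence[10:],
            raw_header=r.raw_header,
        )
        aln = GroupedAlignment.from_records(recs)
        seq, _ = build_focal_consensus(aln, "G1", (1, 30))
        assert seq[9] == backbone_base  # 2-vs-1 majority

    def test_unknown_group_and_bad_region(self, small_alignment):
        aln, _ = small_alignment
        with pytest.raises(UnknownGroupError):
            build_focal_consensus(aln, "G9", (1, 10))
        with pytest.raises(ValueError):
            build_focal_consensus(aln, "G1", (0, 10))


class TestMaskedTarget:
    def test_marks_match_planted_truth(self, rich_alignment, rich_verdicts):
        aln, truth = rich_alignment
        target = make_masked_target(aln, rich_verdicts, "G1", (1, 900))
        dash_cols = {target.column_map[i] for i in target.specific_positions}
        assert dash_cols == truth["G1"]
        star_cols = {target.column_map[i] for i in target.conserved_positions}
        assert star_cols.isdisjoint(dash_cols)
        for col in star_cols:
            assert rich_verdicts[col - 1].conserved_common

    def test_gap_signature_columns_not_marked(self, rich_alignment, rich_verdicts):
        """G3's conserved deletion is specific but vanishes on degap: no
        '-' mark may point at it."""
        aln, truth = rich_alignment
        target = make_masked_target(aln, rich_verdicts, "G3", (1, 900))
        gap_cols = set(range(700, 707))
        assert gap_cols <= truth["G3"]
        assert not gap_cols & set(target.column_map)
        dash_cols = {target.column_map[i] for i in target.specific_positions}
        assert dash_cols == truth["G3"] - gap_cols

    def test_column_map_strictly_increasing(self, rich_alignment, rich_verdicts):
        aln, _ = rich_alignment
        target = make_masked_target(aln, rich_verdicts, "G2", (101, 500))
        assert list(target.column_map) == sorted(set(target.column_map))
        assert target.column_map[0] >= 101 and target.column_map[-1] <= 500

    def test_oversized_region_rejected(self):
        aln, _ = generate_alignment(
            PlantPlan(n_groups=2, strains_per_group=1, n_columns=2100, seed=2)
        )
        verdicts = classify_alignment(aln)
        with pytest.raises(RegionSizeError):
            make_masked_target(aln, verdicts, "G1", (1, 2100))


class TestMaskedFile:
    def test_file_round_trips(self, rich_alignment, rich_verdicts, tmp_path):
        aln, _ = rich_alignment
        path = tmp_path / "g1.txt"
        target = make_primerexplorer_input(
            aln, rich_verdicts, "G1", (1, 900), path
        )
        seq, ann = read_masked_target(path)
        assert seq == target.target_sequence
        assert ann == target.annotation

    def test_blocks_are_length_matched(self, rich_alignment, rich_verdicts, tmp_path):
        aln, _ = rich_alignment
        path = tmp_path / "g2.txt"
        make_primerexplorer_input(aln, rich_verdicts, "G2", (1, 900), path)
        lines = path.read_text().splitlines()
        body = [l for l in lines if not l.startswith(";")]
        for seq_line, ann_line in zip(body[::2], body[1::2]):
            assert len(ann_line) <= len(seq_line) <= 60

    def test_crlf_and_lf_differ_only_in_terminators(
        self, rich_alignment, rich_verdicts, tmp_path
    ):
        aln, _ = rich_alignment
        target = make_masked_target(aln, rich_verdicts, "G1", (1, 900))
        unix = tmp_path / "unix.txt"
        win = tmp_path / "win.txt"
        write_masked_target(target, unix, line_endings="unix")
        write_masked_target(target, win, line_endings="windows")
        raw_unix = unix.read_bytes()
        raw_win = win.read_bytes()
        assert b"\r" not in raw_unix
        assert raw_win.count(b"\n") == raw_win.count(b"\r\n")
        assert raw_win.replace(b"\r\n", b"\n") == raw_unix

    def test_fully_conserved_alignment_marks_all_stars(self, tmp_path):
        aln, _ = generate_alignment(
            PlantPlan(n_groups=2, strains_per_group=2, n_columns=100, seed=8)
        )
        verdicts = classify_alignment(aln)
        target = make_masked_target(aln, verdicts, "G1", (1, 100))
        assert set(target.annotation) == {"*"}


class TestBundle:
    def _files(self, tmp_path, n=3):
        paths = []
        for i in range(n):
            p = tmp_path / f"out{i}.txt"
            p.write_text(f"file {i}\n")
            paths.append(p)
        return paths

    def test_directory_bundle(self, tmp_path):
        files = self._files(tmp_path)
        dest = bundle_outputs(files, tmp_path / "bundle", "proj1")
        assert sorted(p.name for p in dest.iterdir()) == [
            "out0.txt",
            "out1.txt",
            "out2.txt",
        ]

    def test_zip_bundle_has_same_manifest(self, tmp_path):
        files = self._files(tmp_path)
        archive = bundle_outputs(files, tmp_path / "bundle", "proj1", zip=True)
        with zipfile.ZipFile(archive) as zf:
            names = sorted(n.split("/")[-1] for n in zf.namelist())
        assert names == ["out0.txt", "out1.txt", "out2.txt"]

    def test_collision_without_overwrite(self, tmp_path):
        files = self._files(tmp_path)
        bundle_outputs(files, tmp_path / "bundle", "proj1")
        with pytest.raises(OutputCollisionError):
            bundle_outputs(files, tmp_path / "bundle", "proj1")
        bundle_outputs(files, tmp_path / "bundle", "proj1", overwrite=True)
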