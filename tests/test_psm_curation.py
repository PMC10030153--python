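import itertools

import pytest

from surfacer.proteome_io import ProteinRecord, TopologyAnnotation
from surfacer.psm_curation import (
    ClassificationResult,
    Modification,
    ProteinEvidenceSummary,
    PsmError,
    PsmRecord,
    assign_master_proteins,
    classify_surface,
    compute_specificity,
    flag_scm_deamidation,
    infer_orientation,
    parse_psm_table,
    curation_report,
)

DEAM = Modification(4, "Deamidated", 0.98402)


def _psm(spectrum_id, peptide, mods=(), accessions=("P1",)):
    return PsmRecord(spectrum_id, peptide, tuple(mods), tuple(accessions))


# ---------------------------------------------------------------------------
# parsing

class TestParsePsmTable:
    def _write(self, tmp_path, rows, header="spectrum_id\tpeptide\tmodifications\tproteins"):
        path = tmp_path / "psms.tsv"
        path.write_text(header + "\n" + "\n".join(rows) + "\n")
        return path

    def test_pd_dialect_modification_string(self, tmp_path):
        path = self._write(tmp_path, ["s1\tAAANGTK\t1xDeamidated [N4]\tP1"])
        records, n_bad = parse_psm_table(path, dialect="pd")
        assert n_bad == 0
        (mod,) = records[0].modifications
        assert (mod.position, mod.delta) == (4, pytest.approx(0.98402))
        assert mod.is_deamidation()

    def test_pd_dialect_multisite(self, tmp_path):
        path = self._write(
            tmp_path, ["s1\tACANCTK\t2xCarbamidomethyl [C2; C5]; 1xDeamidated [N4]\tP1"]
        )
        records, _ = parse_psm_table(path, dialect="pd")
        assert [m.position for m in records[0].modifications] == [2, 5, 4]

    def test_generic_dialect_and_empty_mods(self, tmp_path):
        path = self._write(
            tmp_path, ["s1\tAAANGTK\t4|Deamidated|0.98402\tP1;P2", "s2\tAAAK\t\tP1"]
        )
        records, n_bad = parse_psm_table(path)
        assert n_bad == 0
        assert records[0].accessions == ("P1", "P2")
        assert records[1].modifications == ()

    def test_missing_column_is_schema_error(self, tmp_path):
        path = self._write(tmp_path, ["s1\tx"], header="spectrum_id\tmodifications")
        with pytest.raises(PsmError, match="missing columns"):
            parse_psm_table(path)

    def test_bad_rows_counted_not_fatal(self, tmp_path):
        path = self._write(
            tmp_path,
            [
                "s1\tAAANGTK\t4|Deamidated|0.98402\tP1",
                "s2\tAAANGTK\tgarbage\tP1",
                "s3\tAAK\t9|Deamidated|0.98402\tP1",  # position beyond peptide
            ],
        )
        records, n_bad = parse_psm_table(path)
        assert len(records) == 1 and n_bad == 2


# ---------------------------------------------------------------------------
# sequon-deamidation evidence

class TestFlagScmDeamidation:
    def test_motif_inside_peptide(self, simple_proteins):
        # P1 = MKAAANGTKLLNGSAVKAAAK; peptide AAANGTK starts at protein pos 3
        evidence = flag_scm_deamidation(_psm("s1", "AAANGTK", [DEAM]), simple_proteins)
        assert [(e.accession, e.position, e.motif) for e in evidence] == [
            ("P1", 6, "NGT")
        ]
        assert evidence[0].psm_ids == ("s1",)

    def test_motif_window_spans_peptide_boundary(self):
        proteins = {"P3": ProteinRecord("P3", "", "KAANASLLK")}
        # peptide ends at the N; S/T of the sequon lies beyond its C-terminus
        psm = _psm("s2", "AAN", [Modification(3, "Deamidated", 0.98402)], ("P3",))
        evidence = flag_scm_deamidation(psm, proteins)
        assert [(e.position, e.motif) for e in evidence] == [(4, "NAS")]

    def test_proline_blocks_motif(self, simple_proteins):
        psm = _psm("s3", "AANPSK", [Modification(3, "Deamidated", 0.98402)], ("P2",))
        assert flag_scm_deamidation(psm, simple_proteins) == []

    def test_non_deamidated_or_non_n_mod_ignored(self, simple_proteins):
        oxidation = Modification(4, "Oxidation", 15.994915)
        assert flag_scm_deamidation(_psm("s4", "AAANGTK", [oxidation]), simple_proteins) == []
        # deamidation positioned on a non-N residue is not glycosite evidence
        mod = Modification(1, "Deamidated", 0.98402)
        assert flag_scm_deamidation(_psm("s5", "AAANGTK", [mod]), simple_proteins) == []

    def test_unlocatable_peptide_is_error(self, simple_proteins):
        mod = Modification(5, "Deamidated", 0.98402)  # the N of WWWWNGTK
        with pytest.raises(PsmError, match="not found"):
            flag_scm_deamidation(_psm("s6", "WWWWNGTK", [mod]), simple_proteins)

    def test_evidence_residue_is_always_n(self, simple_proteins):
        for psm in [
            _psm("a", "AAANGTK", [DEAM]),
            _psm("b", "LLNGSAVK", [Modification(3, "Deamidated", 0.98402)]),
        ]:
            for ev in flag_scm_deamidation(psm, simple_proteins):
                assert simple_proteins[ev.accession].residue(ev.position) == "N"


# ---------------------------------------------------------------------------
# master proteins and specificity

class TestMasterProteins:
    def test_unique_peptide_makes_master(self, simple_proteins):
        summaries = assign_master_proteins(
            [_psm("s1", "AAANGTK", [DEAM], ("P1",))], simple_proteins
        )
        assert set(summaries) == {"P1"}
        assert summaries["P1"].n_unique_peptides == 1
        assert summaries["P1"].n_psms_scm == 1

    def test_shared_only_protein_grouped_under_master(self, simple_proteins):
        psms = [
            _psm("s1", "AAANGTK", [DEAM], ("P1",)),
            _psm("s2", "LLNGSAVK", [], ("P1", "P2")),
        ]
        summaries = assign_master_proteins(psms, simple_proteins)
        assert set(summaries) == {"P1"}
        assert summaries["P1"].grouped_accessions == ("P2",)
        assert summaries["P1"].n_psms_total == 2

    def test_identical_peptide_sets_collapse_lexicographically(self, simple_proteins):
        psms = [_psm("s1", "AAANGTK", [DEAM], ("P9", "P1"))]
        summaries = assign_master_proteins(psms, simple_proteins)
        assert set(summaries) == {"P1"}

    def test_empty_psm_list_is_error(self, simple_proteins):
        with pytest.raises(PsmError):
            assign_master_proteins([], simple_proteins)


class TestSpecificity:
    def test_psm_and_protein_levels(self, simple_proteins):
        psms = [
            _psm(f"scm{i}", "AAANGTK", [DEAM], ("P1",)) for i in range(8)
        ] + [_psm(f"bg{i}", "AANPSK", [], ("P2",)) for i in range(2)]
        summaries = assign_master_proteins(psms, simple_proteins)
        report = compute_specificity(summaries, psms, simple_proteins)
        assert report.psm_level == pytest.approx(80.0)
        assert report.n_psms_scm == 8 and report.n_psms_total == 10
        assert report.protein_level == pytest.approx(50.0)  # P1 of {P1, P2}

    def test_all_scm_gives_100(self, simple_proteins):
        psms = [_psm("s1", "AAANGTK", [DEAM], ("P1",))]
        summaries = assign_master_proteins(psms, simple_proteins)
        report = compute_specificity(summaries, psms, simple_proteins)
        assert report.psm_level == 100.0 and report.protein_level == 100.0

    def test_zero_denominator_is_error(self, simple_proteins):
        with pytest.raises(PsmError):
            compute_specificity({}, [], simple_proteins)


# ---------------------------------------------------------------------------
# classification

def _summary(cirfess, spc, sp):
    return ProteinEvidenceSummary(
        accession="P", cirfess_score=cirfess, spc_score=spc, signal_peptide=sp
    )


def test_classification_examples():
    assert classify_surface(_summary(2, 0, False)) == ClassificationResult(
        "P", True, "cirfess_positive"
    )
    assert classify_surface(_summary(0, 3, False)).branch == "spc_consensus"
    assert classify_surface(_summary(0, 2, True)).branch == "signal_peptide"
    assert classify_surface(_summary(0, 2, False)) == ClassificationResult(
        "P", False, "none"
    )


def test_classification_matches_truth_table():
    """Decision rule equals exhaustive enumeration over every cell."""
    for cirfess, spc, sp in itertools.product((0, 1), range(5), (False, True)):
        expected = (cirfess > 0) or (cirfess == 0 and spc in (3, 4)) or (
            cirfess == 0 and sp
        )
        verdict = classify_surface(_summary(cirfess, spc, sp))
        assert verdict.is_surface == expected
        assert (verdict.branch != "none") == expected


# ---------------------------------------------------------------------------
# orientation

TM_SINGLE = TopologyAnnotation("P1", "predictor-A", ((50, 70, "transmembrane"),))
TM_DOUBLE = TopologyAnnotation(
    "P1", "predictor-A", ((50, 70, "transmembrane"), (100, 120, "transmembrane"))
)


def test_orientation_single_tm_n_out_consistent():
    verdict = infer_orientation([30, 35], TM_SINGLE, database_orientation="N-out")
    assert verdict.inferred == "N-out" and verdict.status == "consistent"


def test_orientation_both_sides_conflict():
    verdict = infer_orientation([30, 90], TM_SINGLE)
    assert verdict.inferred == "conflict" and verdict.status == "conflict"


def test_orientation_no_sites_undetermined():
    verdict = infer_orientation([], TM_SINGLE, database_orientation="N-in")
    assert verdict.inferred == "undetermined" and verdict.status == "undetermined"


def test_orientation_parity_across_two_tms():
    # site after the second TM shares the N-terminal side again
    verdict = infer_orientation([30, 130], TM_DOUBLE, database_orientation="N-out")
    assert verdict.inferred == "N-out" and verdict.status == "consistent"
    assert infer_orientation([85], TM_DOUBLE).inferred == "N-in"


def test_orientation_site_in_tm_excluded_and_order_invariant():
    verdict = infer_orientation([60, 30, 30], TM_SINGLE)
    assert verdict.excluded_sites == (60,)
    assert verdict.inferred == "N-out"
    assert verdict == infer_orientation([30, 60, 30], TM_SINGLE)


def test_orientation_database_mismatch_is_conflict():
    verdict = infer_orientation([30], TM_SINGLE, database_orientation="N-in")
    assert verdict.status == "conflict"


def test_orientation_requires_tm():
    soluble = TopologyAnnotation("P1", "predictor-A", ((1, 40, "extracellular"),))
    with pytest.raises(ValueError):
        infer_orientation([10], soluble)


# ---------------------------------------------------------------------------
# report bundle

def test_curation_report_tables(simple_proteins):
    psms = [
        _psm("s1", "AAANGTK", [DEAM], ("P1",)),
        _psm("s2", "MSSTTK", [], ("P2",)),
    ]
    summaries = assign_master_proteins(psms, simple_proteins)
    summaries["P1"].cirfess_score = 1
    classifications = {a: classify_surface(s) for a, s in summaries.items()}
    report = curation_report(summaries, classifications)
    # SCM table: only masters with sequon evidence; filtered: surface subset
    assert list(report["scm"]["accession"]) == ["P1"]
    assert list(report["scm_filtered"]["accession"]) == ["P1"]
    assert set(report["scm_filtered"]["accession"]) <= set(report["scm"]["accession"])
    assert list(report["glycosites"]["position"]) == [6]


def test_curation_report_empty_pass(simple_proteins):
    psms = [_psm("s1", "AAANGTK", [DEAM], ("P1",))]
    summaries = assign_master_proteins(psms, simple_proteins)  # cirfess stays 0
    classifications = {a: classify_surface(s) for a, s in summaries.items()}
    report = curation_report(summaries, classifications)
    assert len(report["scm"]) == 1
    assert len(report["scm_filtered"]) == 0
    assert list(report["scm_filtered"].columns) == list(report["scm"].columns)
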