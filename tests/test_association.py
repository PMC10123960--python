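import numpy as np
import pandas as pd
import pytest

import specgwas as sg
from specgwas.association import (CLASS_THRESHOLDS, MarkerHit, hits_table,
                                  read_gene_annotation)


@pytest.fixture
def pips():
    return {"Chr1_100": 0.05, "Chr1_200": 0.12, "Chr2_300": 0.60}


class TestSelectMarkers:
    def test_threshold_010(self, pips):
        hits = sg.select_markers(pips, 0.10)
        assert [h.marker_id for h in hits] == ["Chr2_300", "Chr1_200"]
        assert all(h.threshold_used == 0.10 for h in hits)

    def test_threshold_050(self, pips):
        hits = sg.select_markers(pips, 0.50)
        assert [h.marker_id for h in hits] == ["Chr2_300"]

    def test_empty_result_valid(self, pips):
        assert sg.select_markers(pips, 0.99) == []

    def test_monotone_in_threshold(self, rng):
        vals = {f"Chr1_{i * 100}": p for i, p in
                enumerate(rng.random(50), start=1)}
        strict = {h.marker_id for h in sg.select_markers(vals, 0.50)}
        lenient = {h.marker_id for h in sg.select_markers(vals, 0.10)}
        assert strict <= lenient

    def test_invalid_pip_rejected(self):
        with pytest.raises(ValueError, match="0, 1"):
            sg.select_markers({"Chr1_1": 1.2}, 0.1)

    def test_hit_below_threshold_rejected(self):
        with pytest.raises(ValueError, match="below"):
            MarkerHit("Chr1_1", "Chr1", 1, "PH", "B+", pip=0.05,
                      threshold_used=0.10)


@pytest.fixture
def annotation():
    return pd.DataFrame([
        # gene ending exactly at window start: still overlaps (closed)
        {"gene_id": "gA", "chrom": "Chr4", "start": 164_285_000,
         "end": 164_285_549},
        {"gene_id": "gB", "chrom": "Chr4", "start": 164_300_000,
         "end": 164_301_000},
        {"gene_id": "gC", "chrom": "Chr4", "start": 164_385_550,
         "end": 164_386_000},  # one bp past window end: excluded
        {"gene_id": "gD", "chrom": "Chr5", "start": 164_300_000,
         "end": 164_301_000},  # wrong chromosome
    ])


class TestGeneWindow:
    def test_window_arithmetic_50kbp(self, annotation):
        hit = MarkerHit("Chr4_164335549", "Chr4", 164_335_549, "NDVI", "B+",
                        0.6, 0.5, "index")
        gw = sg.gene_window_lookup(hit, annotation, flank_bp=50_000)
        assert gw.window_start_bp == 164_285_549
        assert gw.window_end_bp == 164_385_549
        assert gw.gene_ids == ["gA", "gB"]
        assert gw.n_genes == 2

    def test_window_clipped_at_one(self, annotation):
        hit = MarkerHit("Chr4_10000", "Chr4", 10_000, "PH", "B-", 0.2, 0.1)
        gw = sg.gene_window_lookup(hit, annotation, flank_bp=50_000)
        assert gw.window_start_bp == 1

    def test_absent_chromosome_warns_empty(self, annotation, caplog):
        hit = MarkerHit("Chr9_500", "Chr9", 500, "PH", "B-", 0.2, 0.1)
        with caplog.at_level("WARNING"):
            gw = sg.gene_window_lookup(hit, annotation)
        assert gw.gene_ids == [] and "Chr9" in caplog.text

    def test_matches_brute_force(self, rng):
        ann = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(300)],
            "chrom": rng.choice(["Chr1", "Chr2"], 300),
            "start": (s := rng.integers(1, 10_000_000, 300)),
            "end": s + rng.integers(100, 5_000, 300),
        })
        for pos in rng.integers(1, 10_000_000, 20):
            hit = MarkerHit(f"Chr1_{pos}", "Chr1", int(pos), "PH", "B+",
                            0.5, 0.1)
            got = set(sg.gene_window_lookup(hit, ann, flank_bp=50_000).gene_ids)
            lo, hi = max(int(pos) - 50_000, 1), int(pos) + 50_000
            expect = {r.gene_id for r in ann.itertuples()
                      if r.chrom == "Chr1" and r.end >= lo and r.start <= hi}
            assert got == expect


@pytest.fixture
def pip_matrix():
    rows = []
    for mgmt in ("B-", "B+"):
        for mid in ("Chr1_10", "Chr2_20"):
            for name, cls in [("PH", "manual"), ("R700", "band"),
                              ("NDVI", "index")]:
                pip = 0.8 if (mid, mgmt) == ("Chr1_10", "B+") else 0.02
                rows.append({"marker_id": mid, "phenotype": name,
                             "phenotype_class": cls, "management": mgmt,
                             "pip": pip})
    return pd.DataFrame(rows)


class TestAggregatePhewas:
    def test_counts_match_exhaustive_recount(self, pip_matrix):
        hits = [MarkerHit("Chr1_10", "Chr1", 10, "PH", "B+", 0.8, 0.1)]
        prof = sg.aggregate_phewas(hits, pip_matrix)
        sub = pip_matrix[pip_matrix.marker_id == "Chr1_10"]
        manual = (sub[sub.phenotype_class == "manual"].pip
                  >= CLASS_THRESHOLDS["manual"]).sum()
        hyper = (sub[sub.phenotype_class != "manual"].pip
                 >= CLASS_THRESHOLDS["band"]).sum()
        assert prof["n_phenotypes"].iloc[0] == manual + hyper == 3

    def test_shared_flag_between_classes(self, pip_matrix):
        hits = [MarkerHit("Chr1_10", "Chr1", 10, "PH", "B+", 0.8, 0.1)]
        prof = sg.aggregate_phewas(hits, pip_matrix)
        assert prof.loc[prof.marker_id == "Chr1_10", "shared"].all()

    def test_management_profile_without_selection_returned(self, pip_matrix):
        hits = [MarkerHit("Chr1_10", "Chr1", 10, "PH", "B+", 0.8, 0.1)]
        prof = sg.aggregate_phewas(hits, pip_matrix)
        bminus = prof[(prof.marker_id == "Chr1_10")
                      & (prof.management == "B-")]
        assert len(bminus) == 3 and not bminus["selected"].any()

    def test_empty_hits_rejected(self, pip_matrix):
        with pytest.raises(ValueError, match="nonempty"):
            sg.aggregate_phewas([], pip_matrix)


def test_hits_table_shape(annotation):
    hits = [
        MarkerHit("Chr4_164335549", "Chr4", 164_335_549, "NDVI", "B+",
                  0.6, 0.5, "index"),
        MarkerHit("Chr4_164335549", "Chr4", 164_335_549, "R700", "B+",
                  0.7, 0.5, "band"),
    ]
    table = hits_table(hits, annotation, maf={"Chr4_164335549": 0.27})
    row = table.iloc[0]
    assert row["n_phenotypes"] == 2
    assert row["pip"] == pytest.approx(0.65)
    assert row["maf"] == 0.27
    assert row["n_genes"] == 2


def test_gff3_reader(tmp_path):
    gff = tmp_path / "ann.gff3"
    gff.write_text("##gff-version 3\n"
                   "Chr1\tsrc\tgene\t100\t500\t.\t+\t.\tID=geneA\n"
                   "Chr1\tsrc\tmRNA\t100\t500\t.\t+\t.\tID=tA;Parent=geneA\n"
                   "Chr2\tsrc\tgene\t900\t1200\t.\t-\t.\tID=geneB\n")
    ann = read_gene_annotation(gff)
    assert len(ann) == 2  # mRNA feature ignored
    assert set(ann["gene_id"]) == {"geneA", "geneB"}
    assert ann.loc[ann.gene_id == "geneA", "start"].iloc[0] == 100
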