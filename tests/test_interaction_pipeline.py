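"""Interaction ingestion, filtering, PIR classification and gene lists."""

import numpy as np
import pandas as pd
import pytest

from rnapir.genome_intervals import GenomicInterval, IntervalTrack
from rnapir.interaction_pipeline import (
    SchemaError,
    annotate_tfbs,
    build_contingency,
    classify_pirs,
    gene_lists_by_category,
    is_canonical_chrom,
    load_margi,
    load_pchic,
    pir_track,
    write_gene_lists,
)

PCHIC_COLS = ["bait_chr", "bait_start", "bait_end", "bait_genes", "pir_chr", "pir_start", "pir_end"]
MARGI_COLS = ["rna_chr", "rna_start", "rna_end", "dna_chr", "dna_start", "dna_end"]


def _write(tmp_path, name, rows, cols):
    p = tmp_path / name
    pd.DataFrame(rows, columns=cols).to_csv(p, sep="\t", index=False)
    return p


class TestLoadPchic:
    def test_toy_file_counts_and_filters(self, tmp_path):
        rows = [
            ("chr1", 0, 100, "GENE1", "chr1", 500, 600),
            ("chr1", 0, 100, "GENE2", "chr1", 800, 900),
            ("chr1", 200, 300, "GENE2", "chr1", 500, 600),   # shares PIR with row 1
            ("chr1", 0, 100, "GENE3", "chr2", 500, 600),     # interchromosomal
            ("chr2", 0, 100, "GENE4", "chr2", 700, 800),
            ("chr2", 0, 100, "GENE4", "chr2", 900, 950),
        ]
        inter, records = load_pchic(_write(tmp_path, "p.tsv", rows, PCHIC_COLS))
        assert len(inter) == 5  # interchromosomal row dropped
        assert len(records) == 4  # unique PIRs
        shared = next(r for r in records if r.pir == GenomicInterval("chr1", 500, 600))
        assert shared.genes == ("GENE1", "GENE2")  # union of bait genes

    def test_missing_column_is_schema_error(self, tmp_path):
        p = tmp_path / "bad.tsv"
        pd.DataFrame({"x": [1]}).to_csv(p, sep="\t", index=False)
        with pytest.raises(SchemaError, match="missing required column"):
            load_pchic(p)


class TestLoadMargi:
    def test_filters_and_dedup(self, tmp_path):
        rows = [
            ("chr1", 0, 100, "chr1", 500, 600),
            ("chr1", 0, 100, "chr1", 500, 600),            # exact duplicate pair
            ("chr1", 200, 300, "chr1", 500, 600),          # distinct pair, same DNA region
            ("chr2", 0, 100, "chr2", 700, 800),
            ("chr1", 0, 100, "chrUn_gl000220", 0, 100),    # unplaced -> removed
        ]
        contacts, regions = load_margi(_write(tmp_path, "m.tsv", rows, MARGI_COLS))
        assert len(contacts) == 3
        assert len(regions) == 2

    @pytest.mark.parametrize(
        "chrom,keep",
        [
            ("chr1", True), ("chrX", True), ("chrM", True),
            ("chrUn_gl000220", False), ("chr1_gl000191_random", False),
            ("chr23", False), ("scaffold_1", False),
        ],
    )
    def test_canonical_chromosome_rule(self, chrom, keep):
        assert is_canonical_chrom(chrom) is keep

    def test_cleaning_clean_file_changes_nothing(self, tmp_path):
        rows = [("chr1", 0, 100, "chr1", 500, 600), ("chr2", 5, 50, "chr2", 70, 90)]
        p = _write(tmp_path, "clean.tsv", rows, MARGI_COLS)
        c1, r1 = load_margi(p)
        c2, r2 = load_margi(p)
        assert c1 == c2 and r1.intervals == r2.intervals and len(c1) == 2


def _records(triples_and_genes):
    from rnapir.interaction_pipeline import PirRecord

    return [
        PirRecord(pir=GenomicInterval(c, s, e), genes=tuple(g))
        for c, s, e, g in triples_and_genes
    ]


class TestClassifyAnnotate:
    def test_one_bp_overlap_sets_rna_flag(self):
        recs = _records([("chr1", 100, 200, ["A"]), ("chr1", 300, 400, ["B"])])
        rna = IntervalTrack("r", [GenomicInterval("chr1", 199, 250)], sorted=True)
        classify_pirs(recs, rna)
        assert [r.has_rna for r in recs] == [True, False]

    def test_empty_rna_regions_all_false(self):
        recs = _records([("chr1", 0, 10, ["A"])])
        classify_pirs(recs, IntervalTrack("r", [], sorted=True))
        assert recs[0].has_rna is False

    def test_classification_is_idempotent_and_order_invariant(self):
        rng = np.random.default_rng(1)
        base = [("chr1", int(s), int(s) + 50, ["G"]) for s in rng.integers(0, 5000, 30) * 100]
        rna = IntervalTrack(
            "r", sorted(GenomicInterval("chr1", int(s), int(s) + 60) for s in rng.integers(0, 500_000, 40)),
            sorted=True,
        )
        recs1 = _records(base)
        classify_pirs(recs1, rna)
        classify_pirs(recs1, rna)  # idempotent
        recs2 = _records(base[::-1])
        classify_pirs(recs2, rna)
        m1 = {r.pir: r.has_rna for r in recs1}
        m2 = {r.pir: r.has_rna for r in recs2}
        assert m1 == m2

    def test_annotate_unknown_factor_errors(self):
        recs = _records([("chr1", 0, 10, ["A"])])
        with pytest.raises(ValueError, match="unknown factor"):
            annotate_tfbs(recs, IntervalTrack("c", [], sorted=True), "gata4")

    def test_annotate_matches_brute_force(self):
        rng = np.random.default_rng(8)
        recs = _records(
            [("chr1", int(s), int(s + rng.integers(50, 400)), ["G"]) for s in rng.integers(0, 50_000, 80)]
        )
        cons = IntervalTrack(
            "c",
            sorted(GenomicInterval("chr1", int(s), int(s) + 30) for s in rng.integers(0, 50_000, 60)),
            sorted=True,
        )
        annotate_tfbs(recs, cons, "ctcf")
        for r in recs:
            assert r.has_ctcf == any(r.pir.overlaps(iv) for iv in cons)


class TestContingencyAndGeneLists:
    def _flagged(self):
        recs = _records(
            [
                ("chr1", 0, 10, ["G1"]), ("chr1", 20, 30, ["G2"]),
                ("chr1", 40, 50, ["G3"]), ("chr1", 60, 70, ["G4"]),
            ]
        )
        for r, (rna, tf) in zip(recs, [(1, 1), (1, 0), (0, 1), (0, 0)]):
            r.has_rna, r.has_ctcf = bool(rna), bool(tf)
        return recs

    def test_one_record_per_cell(self):
        ct = build_contingency(self._flagged(), "ctcf")
        assert (ct.a, ct.b, ct.c, ct.d) == (1, 1, 1, 1)
        assert ct.pct_rna_tfbs == 50.0 and ct.pct_nonrna_tfbs == 50.0

    def test_crude_or_closed_form(self):
        # frozen closed form: (10*40)/(20*30) = 2/3
        from rnapir.interaction_pipeline import CountsTable

        ct = CountsTable("ctcf", 10, 20, 30, 40)
        assert ct.crude_odds_ratio == pytest.approx(0.66667, abs=1e-4)
        assert ct.n_rna == 30 and ct.n_nonrna == 70

    def test_cells_sum_to_record_count(self, worked):
        from rnapir.genome_intervals import consensus_intervals

        _, records = load_pchic_from_frame(worked["pchic"])
        classify_from_frames(records, worked)
        ct = build_contingency(records, "ctcf")
        assert ct.a + ct.b + ct.c + ct.d == len(records)

    def test_unset_flag_errors(self):
        recs = _records([("chr1", 0, 10, ["G"])])
        with pytest.raises(ValueError, match="has_rna unset"):
            build_contingency(recs, "ctcf")

    def test_gene_lists_dedupe_within_and_union_across(self):
        recs = _records(
            [
                ("chr1", 0, 10, ["G"]), ("chr1", 20, 30, ["G"]),     # both RNA+/TFBS+
                ("chr1", 40, 50, ["G", "H"]),                         # RNA-/TFBS+
            ]
        )
        flags = [(1, 1), (1, 1), (0, 1)]
        for r, (rna, tf) in zip(recs, flags):
            r.has_rna, r.has_ctcf = bool(rna), bool(tf)
        lists = gene_lists_by_category(recs, "ctcf")
        assert lists["rna_and_tfbs"] == ["G"]          # deduped within list
        assert lists["tfbs_only"] == ["G", "H"]        # G sits in both lists
        assert lists["rna_only"] == [] and lists["neither"] == []

    def test_gene_list_export_one_symbol_per_line(self, tmp_path):
        paths = write_gene_lists({"rna_and_tfbs": ["B", "A"]}, tmp_path, "ctcf")
        assert paths[0].read_text() == "B\nA\n"


# -- helpers shared with the worked fixture ---------------------------------

def load_pchic_from_frame(frame):
    import tempfile

    with tempfile.NamedTemporaryFile("w", suffix=".tsv", delete=False) as fh:
        frame.to_csv(fh.name, sep="\t", index=False)
        return load_pchic(fh.name)


def classify_from_frames(records, worked):
    import tempfile

    from rnapir.genome_intervals import consensus_intervals

    with tempfile.NamedTemporaryFile("w", suffix=".tsv", delete=False) as fh:
        worked["margi"].to_csv(fh.name, sep="\t", index=False)
        _, rna_regions = load_margi(fh.name)
    classify_pirs(records, rna_regions)
    annotate_tfbs(records, consensus_intervals(worked["tracks"]), "ctcf")
    return records


class TestWorkedFixture:
    """The 12-PIR hand-enumerated dataset drives the whole front half."""

    def test_contingency_matches_hand_enumeration(self, worked):
        _, records = load_pchic_from_frame(worked["pchic"])
        assert len(records) == 12
        classify_from_frames(records, worked)
        ct = build_contingency(records, "ctcf")
        exp = worked["expected_counts"]
        assert (ct.a, ct.b, ct.c, ct.d) == (exp["a"], exp["b"], exp["c"], exp["d"])
        assert ct.crude_odds_ratio == pytest.approx(2.0)

    def test_consensus_matches_per_base_oracle(self, worked):
        from rnapir.genome_intervals import consensus_intervals
        from test_genome_intervals import per_base_consensus

        cons = consensus_intervals(worked["tracks"])
        oracle = per_base_consensus(worked["tracks"], span=10_000, chroms=("chr20", "chr21"))
        assert cons.intervals == oracle
        # consensus of exact/+10/-10 copies shrinks each true site by 10 bp per edge
        assert cons.intervals == [
            GenomicInterval(s.chrom, s.start + 10, s.end - 10) for s in sorted(worked["true_sites"])
        ]

    def test_gene_lists_hand_enumeration(self, worked):
        _, records = load_pchic_from_frame(worked["pchic"])
        classify_from_frames(records, worked)
        lists = gene_lists_by_category(records, "ctcf")
        assert lists["rna_and_tfbs"] == ["GATA1", "KLF4", "ZIC2", "ZIC5"]
        assert lists["rna_only"] == ["POU5F1", "SOX2", "TBX3"]
        assert lists["tfbs_only"] == ["KLF4", "NANOG", "PRDM14"]
        assert lists["neither"] == ["ESRRB", "LIN28A", "MYC"]
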