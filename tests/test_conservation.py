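"""Conserved / species-specific gene sets and the enrichment wrappers."""

import numpy as np
import pandas as pd
import pytest

from orthosplice.conservation import (
    build_background,
    conserved_regulated_genes,
    factor_target_enrichment,
    label_genes,
    species_specific_regulated_genes,
    term_enrichment,
)
from orthosplice.compstats import class_enrichment
from orthosplice.differential import DifferentialCall
from orthosplice.events import Condition, ReplicateCounts
from orthosplice.orthologs import OrthologPair


def _pair(i, gene=None):
    g = gene or f"g{i}"
    return OrthologPair(f"src_e{i}", f"tgt_e{i}", f"src_{g}", f"tgt_{g}",
                        (0, 0, 0, 0))


def _call(eid, sig):
    # significant: p < 0.05 and |delta| > 10 with expression passed
    p, d = (0.01, 30.0) if sig else (0.5, 1.0)
    return DifferentialCall(eid, 50.0, 50.0 + d, d, p, passes_expression=True)


def _counts(eid, level, cond=Condition.basal):
    return ReplicateCounts(eid, cond, (level, level, level), (0, 0, 0))


class TestBuildBackground:
    def test_gene_expressed_in_both_included(self):
        pairs = [_pair(1)]
        bg = build_background(pairs, [_counts("tgt_e1", 20)],
                              {"b1": [_counts("src_e1", 20)]})
        assert bg == {"tgt_g1"}

    def test_gene_failing_filter_in_all_b_excluded(self):
        pairs = [_pair(1), _pair(2)]
        with pytest.raises(ValueError, match="empty"):
            build_background(pairs, [_counts("tgt_e1", 20), _counts("tgt_e2", 20)],
                             {"b1": [_counts("src_e1", 2), _counts("src_e2", 3)]})

    def test_planted_background_recovered_exactly(self, small_bundle):
        from orthosplice.simulate import planted_pairs
        pairs = planted_pairs(small_bundle)
        bg = build_background(
            pairs,
            small_bundle.counts[("target", "basal")]
            + small_bundle.counts[("target", "stimulated")],
            {"b1": small_bundle.counts[("source", "basal")]
             + small_bundle.counts[("source", "stimulated")]},
        )
        # at depth 200 every orthologous event passes the mean>5 filter
        expected = {p.target_gene_id for p in pairs}
        assert bg == expected


class TestConservedAndSpecific:
    def setup_method(self):
        self.pairs = [_pair(1), _pair(2), _pair(3), _pair(4)]
        self.background = {"tgt_g1", "tgt_g2", "tgt_g3", "tgt_g4"}

    def test_conserved_needs_any_b_dataset(self):
        calls_a = {"tgt_e1": _call("tgt_e1", True)}
        calls_b = {
            "div4": {"src_e1": _call("src_e1", True)},
            "div10": {"src_e1": _call("src_e1", False)},
        }
        assert conserved_regulated_genes(self.pairs, calls_a, calls_b) == {"tgt_g1"}

    def test_not_conserved_without_b_support(self):
        calls_a = {"tgt_e1": _call("tgt_e1", True)}
        calls_b = {"div4": {"src_e1": _call("src_e1", False)}}
        assert conserved_regulated_genes(self.pairs, calls_a, calls_b) == set()

    def test_gene_level_vs_event_level(self):
        # same gene, different events significant in each species
        pairs = [_pair(1, "gX"), _pair(2, "gX")]
        calls_a = {"tgt_e1": _call("tgt_e1", True),
                   "tgt_e2": _call("tgt_e2", False)}
        calls_b = {"div4": {"src_e1": _call("src_e1", False),
                            "src_e2": _call("src_e2", True)}}
        assert conserved_regulated_genes(pairs, calls_a, calls_b) == {"tgt_gX"}
        assert conserved_regulated_genes(pairs, calls_a, calls_b,
                                         event_level=True) == set()

    def test_species_specific_requires_testable_ortholog(self):
        calls_a = {"tgt_e1": _call("tgt_e1", True),
                   "tgt_e2": _call("tgt_e2", True)}
        calls_b = {"div4": {"src_e1": _call("src_e1", False)}}
        background = {"tgt_g1"}  # g2's ortholog untestable in B
        out = species_specific_regulated_genes(
            self.pairs, calls_a, calls_b, background)
        assert out == {"tgt_g1"}
        permissive = species_specific_regulated_genes(
            self.pairs, calls_a, calls_b, background, include_untested=True)
        assert permissive == {"tgt_g1", "tgt_g2"}

    def test_conserved_gene_not_species_specific(self):
        calls_a = {"tgt_e1": _call("tgt_e1", True)}
        calls_b = {"div4": {"src_e1": _call("src_e1", True)}}
        out = species_specific_regulated_genes(
            self.pairs, calls_a, calls_b, self.background)
        assert out == set()

    def test_labels_partition_regulated_background(self):
        calls_a = {"tgt_e1": _call("tgt_e1", True),
                   "tgt_e2": _call("tgt_e2", True),
                   "tgt_e3": _call("tgt_e3", False)}
        calls_b = {"div4": {"src_e1": _call("src_e1", True),
                            "src_e3": _call("src_e3", True)}}
        labels = label_genes(self.pairs, calls_a, calls_b, self.background)
        by_label = {}
        for lab in labels.values():
            by_label.setdefault(lab.label, set()).add(lab.gene_id)
        assert by_label["conserved"] == {"tgt_g1"}
        assert by_label["species_specific_A"] == {"tgt_g2"}
        assert by_label["species_specific_B"] == {"tgt_g3"}
        assert by_label["unregulated"] == {"tgt_g4"}
        # conserved and species-specific are disjoint and lose no gene
        conserved = conserved_regulated_genes(self.pairs, calls_a, calls_b)
        specific = species_specific_regulated_genes(
            self.pairs, calls_a, calls_b, self.background)
        regulated_a = {"tgt_g1", "tgt_g2"}
        assert conserved | specific == regulated_a
        assert conserved & specific == set()


class TestFactorEnrichment:
    def test_foreground_equal_background_is_null(self):
        bg = {f"e{i}" for i in range(50)}
        targets = {"RBFOX": {f"e{i}" for i in range(10)}}
        res = factor_target_enrichment(targets, bg, bg)["RBFOX"]
        assert res.fold_enrichment == pytest.approx(1.0, abs=0.05)
        assert res.fisher_p == pytest.approx(1.0)

    def test_depleted_targets(self):
        bg = {f"e{i}" for i in range(100)}
        fg = {f"e{i}" for i in range(20)}          # e0..e19
        targets = {"NOVA": {f"e{i}" for i in range(50, 80)}}  # disjoint from fg
        res = factor_target_enrichment(targets, fg, bg)["NOVA"]
        assert res.fold_enrichment < 1.0

    def test_shares_arithmetic_with_class_enrichment(self):
        bg = {f"e{i}" for i in range(40)}
        fg = {f"e{i}" for i in range(12)}
        targets = {f"e{i}" for i in range(6, 24)}
        res = factor_target_enrichment({"F": targets}, fg, bg)["F"]
        ref = class_enrichment(targets & bg, fg, bg)
        assert res == ref

    def test_planted_target_enrichment_recovered(self):
        """Targets planted at 3x relative frequency in the foreground."""
        rng = np.random.default_rng(21)
        n = 5000
        bg = {f"e{i}" for i in range(n)}
        fg = {f"e{i}" for i in range(n) if rng.random() < 0.1}
        targets = set()
        for i in range(n):
            eid = f"e{i}"
            p = 0.45 if eid in fg else 0.15  # 3x target rate in foreground
            if rng.random() < p:
                targets.add(eid)
        res = factor_target_enrichment({"F": targets}, fg, bg)["F"]
        # fold enrichment of targets in fg vs non-fg
        fold_of_targets = class_enrichment(targets, fg, bg).fold_enrichment
        assert 2.5 <= fold_of_targets <= 3.5
        assert res.fisher_p < 1e-10


class TestTermEnrichment:
    def test_term_matching_gene_set_has_minimal_p(self):
        bg = {f"g{i}" for i in range(100)}
        gene_set = {f"g{i}" for i in range(10)}
        g2t = {g: {"T_exact"} for g in gene_set}
        for g in list(bg - gene_set)[:40]:
            g2t.setdefault(g, set()).add("T_other")
        frame = term_enrichment(gene_set, bg, g2t)
        assert frame.iloc[0]["term"] == "T_exact"

    def test_small_terms_skipped(self):
        bg = {f"g{i}" for i in range(20)}
        g2t = {"g0": {"tiny"}, "g1": {"tiny"}}
        frame = term_enrichment({"g0"}, bg, g2t, min_genes=5)
        assert frame.empty

    def test_empty_gene_set_no_rows_significant(self):
        bg = {f"g{i}" for i in range(30)}
        g2t = {g: {"T"} for g in list(bg)[:10]}
        frame = term_enrichment(set(), bg, g2t)
        assert (frame["a"] == 0).all()

    def test_null_p_values_roughly_uniform(self):
        """Annotation independent of the gene set: Fisher p has no excess of small values."""
        from scipy.stats import kstest
        rng = np.random.default_rng(3)
        bg = {f"g{i}" for i in range(400)}
        gene_set = set(rng.choice(sorted(bg), size=80, replace=False))
        g2t = {}
        for t in range(150):
            members = rng.choice(sorted(bg), size=40, replace=False)
            for g in members:
                g2t.setdefault(g, set()).add(f"T{t:03d}")
        frame = term_enrichment(gene_set, bg, g2t)
        # discrete p-values are conservative; check no inflation of small p
        assert (frame["fisher_p"] < 0.05).mean() < 0.10
        assert frame["fisher_p"].median() > 0.3

    def test_dataframe_input_accepted(self):
        bg = {"g1", "g2", "g3", "g4", "g5", "g6"}
        df = pd.DataFrame({"gene_id": sorted(bg), "term_id": ["T"] * 6})
        frame = term_enrichment({"g1"}, bg, df, min_genes=5)
        assert len(frame) == 1 and frame.iloc[0]["n_annotated"] == 6

    def test_bh_flag_adds_q_values(self):
        bg = {f"g{i}" for i in range(50)}
        g2t = {g: {"T1"} for g in list(bg)[:20]}
        g2t.update({g: {"T2"} for g in list(bg)[20:45]})
        frame = term_enrichment({"g0", "g1"} & bg, bg, g2t, bh_correct=True)
        assert "q_value" in frame.columns
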