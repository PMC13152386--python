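"""Presence thresholding and taxon-rank specificity scores."""

import numpy as np
import pandas as pd
import pytest

from replichar.io_formats import HitTable, TaxonGrouping
from replichar.specificity import (presence_from_hits, score_all,
                                   specificity_score, summarize_by_replicon)
from replichar.synthetic_data import (TIER_PRESENCE, embleya_preset,
                                      predicted_statistics)

HIT_COLUMNS = ["query_id", "subject_id", "percent_identity", "alignment_length",
               "evalue", "bitscore", "query_length", "subject_genome"]


def _hits(rows):
    return HitTable(rows=pd.DataFrame(rows, columns=HIT_COLUMNS))


class TestPresence:
    def test_passing_hit_is_present(self):
        table = _hits([("q1", "g1|p", 30.0, 60, 1e-10, 100.0, 100, "g1")])
        mat = presence_from_hits(table, {"q1": "r1"}, genomes=["g1"])
        assert bool(mat.matrix.loc["q1", "g1"])

    def test_identity_below_threshold_is_absent(self):
        table = _hits([("q1", "g1|p", 20.0, 60, 1e-10, 100.0, 100, "g1")])
        mat = presence_from_hits(table, {"q1": "r1"}, genomes=["g1"])
        assert not bool(mat.matrix.loc["q1", "g1"])

    def test_coverage_and_evalue_thresholds(self):
        low_cov = _hits([("q1", "g1|p", 90.0, 40, 1e-10, 100.0, 100, "g1")])
        assert not bool(presence_from_hits(low_cov, {"q1": "r"},
                                           genomes=["g1"]).matrix.loc["q1", "g1"])
        bad_e = _hits([("q1", "g1|p", 90.0, 90, 0.01, 100.0, 100, "g1")])
        assert not bool(presence_from_hits(bad_e, {"q1": "r"},
                                           genomes=["g1"]).matrix.loc["q1", "g1"])

    def test_missing_query_length_skips_coverage(self):
        table = _hits([("q1", "g1|p", 90.0, 10, 1e-10, 100.0, None, "g1")])
        mat = presence_from_hits(table, {"q1": "r1"}, genomes=["g1"])
        assert bool(mat.matrix.loc["q1", "g1"])
        assert not mat.coverage_checked

    def test_no_hits_gives_all_false(self):
        mat = presence_from_hits(_hits([]), {"q1": "r1"}, genomes=["g1", "g2"])
        assert not mat.matrix.to_numpy().any()

    def test_matrix_equals_generator_truth(self, embleya_dataset):
        """Thresholding the synthetic hit table recovers the generator's
        presence matrix exactly."""
        ds = embleya_dataset
        q2r = {c.locus_tag: r.id for r in ds.genome.replicons for c in r.cds_list}
        mat = presence_from_hits(ds.hit_table, q2r, genomes=list(ds.grouping.labels),
                                 focal_genome="FOCAL")
        truth = ds.truth.presence
        aligned = mat.matrix.loc[truth.index, truth.columns]
        assert aligned.equals(truth)


class TestScore:
    @pytest.mark.parametrize("fa,fb,expected", [
        (1.0, 0.0, 1.0),       # unique to group A
        (1.0, 1.0, 0.5),       # ubiquitous
        (0.5, 0.25, 1.0 / 3),  # hand evaluation of fA^2/(fA+fB)
    ])
    def test_values(self, fa, fb, expected):
        assert specificity_score(fa, fb) == pytest.approx(expected)

    def test_alternative_formula(self):
        assert specificity_score(1.0, 0.0, formula="alt") == pytest.approx(0.5)
        assert specificity_score(0.5, 0.25, formula="alt") == pytest.approx(0.4)

    def test_undefined_at_zero_zero(self):
        with pytest.raises(ValueError):
            specificity_score(0.0, 0.0)

    def test_bounds_and_monotonicity_on_grid(self):
        grid = np.linspace(0.05, 1.0, 20)
        for fa in grid:
            scores_fb = [specificity_score(fa, fb) for fb in grid]
            assert all(0.0 <= s <= 1.0 for s in scores_fb)
            assert all(a > b for a, b in zip(scores_fb, scores_fb[1:]))  # dec. in fB
        for fb in grid:
            scores_fa = [specificity_score(fa, fb) for fa in grid]
            assert all(a < b for a, b in zip(scores_fa, scores_fa[1:]))  # inc. in fA


class TestScoreAll:
    def _matrix_and_grouping(self, present_in):
        genomes = ["FOCAL"] + [f"B{i}" for i in range(10)]
        mat = pd.DataFrame(False, index=["p1"], columns=genomes)
        for g in present_in:
            mat.loc["p1", g] = True
        from replichar.specificity import PresenceMatrix
        labels = {"FOCAL": ("s0", "gA", "fA")}
        labels.update({f"B{i}": (f"s{i + 1}", f"gB{i}", f"fB{i}") for i in range(10)})
        return (PresenceMatrix(matrix=mat, query_to_replicon={"p1": "r1"}),
                TaxonGrouping(labels=labels, focal_genome="FOCAL"))

    def test_focal_only_protein_scores_one(self):
        matrix, grouping = self._matrix_and_grouping(["FOCAL"])
        rec = score_all(matrix, grouping, "strain")[0]
        assert (rec.fA, rec.fB, rec.score) == (1.0, 0.0, 1.0)

    def test_ubiquitous_protein_scores_half(self):
        matrix, grouping = self._matrix_and_grouping(
            ["FOCAL"] + [f"B{i}" for i in range(10)])
        rec = score_all(matrix, grouping, "strain")[0]
        assert rec.score == pytest.approx(0.5)

    def test_scores_equal_closed_form_on_synthetic_pangenome(self, embleya_dataset):
        """Scores computed through the pipeline equal fA^2/(fA+fB) evaluated
        on the truth presence matrix."""
        ds = embleya_dataset
        q2r = {c.locus_tag: r.id for r in ds.genome.replicons for c in r.cds_list}
        mat = presence_from_hits(ds.hit_table, q2r, genomes=list(ds.grouping.labels),
                                 focal_genome="FOCAL")
        records = score_all(mat, ds.grouping, "strain")
        truth = ds.truth.presence
        group_a, group_b = ds.grouping.groups("strain")
        for rec in records[::17]:  # a systematic sample is plenty
            fa = truth.loc[rec.protein_id, group_a].mean()
            fb = truth.loc[rec.protein_id, group_b].mean()
            assert rec.fA == pytest.approx(fa) and rec.fB == pytest.approx(fb)
            assert rec.score == pytest.approx(fa * fa / (fa + fb))

    def test_tier_medians_ordered_at_strain_level(self, embleya_dataset):
        """strain-unique > genus-core > family-core > universal in median
        strain-level specificity."""
        ds = embleya_dataset
        q2r = {c.locus_tag: r.id for r in ds.genome.replicons for c in r.cds_list}
        mat = presence_from_hits(ds.hit_table, q2r, genomes=list(ds.grouping.labels),
                                 focal_genome="FOCAL")
        records = score_all(mat, ds.grouping, "strain")
        by_tier = {}
        for rec in records:
            tier = ds.truth.gene_tier[rec.protein_id]
            by_tier.setdefault(tier, []).append(rec.score)
        medians = {t: np.median(v) for t, v in by_tier.items()}
        assert medians["strain-unique"] > medians["genus-core"] > \
            medians["family-core"] > medians["universal"]

    def test_medians_near_generator_expectation(self, embleya_dataset):
        ds = embleya_dataset
        expected = predicted_statistics(embleya_preset()[0])["expected_specificity"]
        q2r = {c.locus_tag: r.id for r in ds.genome.replicons for c in r.cds_list}
        mat = presence_from_hits(ds.hit_table, q2r, genomes=list(ds.grouping.labels),
                                 focal_genome="FOCAL")
        records = score_all(mat, ds.grouping, "strain")
        scores = [r.score for r in records
                  if ds.truth.gene_tier[r.protein_id] == "strain-unique"]
        assert np.median(scores) == pytest.approx(
            expected["strain-unique"]["strain"]["score"], abs=0.05)


class TestSummaries:
    def _records(self, scores, replicon="r1", level="strain"):
        from replichar.specificity import SpecificityRecord
        return [SpecificityRecord(protein_id=f"p{i}", replicon_id=replicon,
                                  level=level, fA=1.0, fB=0.0, score=s)
                for i, s in enumerate(scores)]

    def test_constant_scores(self):
        s = summarize_by_replicon(self._records([1.0, 1.0, 1.0]))[0]
        assert (s.median, s.q1, s.q3, s.n) == (1.0, 1.0, 1.0, 3)

    def test_median_interpolation(self):
        s = summarize_by_replicon(self._records([0.5, 0.75, 1.0]))[0]
        assert s.median == pytest.approx(0.75)
        assert s.q1 <= s.median <= s.q3

    def test_chromosome_like_replicon_has_higher_genus_median(self, embleya_dataset):
        """The secondary-chromosome-like replicon carries genus-tier genes, so
        its genus-level median exceeds the strain-specific plasmids'."""
        ds = embleya_dataset
        q2r = {c.locus_tag: r.id for r in ds.genome.replicons for c in r.cds_list}
        mat = presence_from_hits(ds.hit_table, q2r, genomes=list(ds.grouping.labels),
                                 focal_genome="FOCAL")
        records = score_all(mat, ds.grouping, "genus")
        summaries = {s.replicon_id: s for s in summarize_by_replicon(records)}
        assert summaries["EEC1"].median > summaries["EEC2"].median
        assert summaries["EEC1"].median > summaries["EEC3"].median
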