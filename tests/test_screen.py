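"""Screen pipeline stages: queries, scoring, cutoff, concordance, ranking."""

import numpy as np
import pandas as pd
import pytest

from geroscreen import (
    Intervention,
    InterventionList,
    PertType,
    TargetAnnotation,
    ValidationError,
    apply_cutoff,
    build_queries,
    build_query,
    build_self_query,
    run_screen,
    score_compounds,
    simulate_signature_universe,
    tally_and_rank,
    target_concordance_filter,
)
from geroscreen.screen import HitMatrix, MissingSignatureError

from conftest import SMALL_PARAMS, make_sigset


def kd(pert_id, gene, line="default"):
    return dict(pert_ids=[pert_id], pert_types=[PertType.KNOCKDOWN],
                target_genes=[gene], cell_line=line)


class TestBuildQuery:
    def test_k1_picks_argmax_and_argmin(self):
        z = np.array([[0.1], [2.0], [-3.0], [0.5], [1.0]])
        sig = make_sigset(z, **kd("akt_kd", "g1"))
        qs = build_query(sig, Intervention("AKT", "g1", PertType.KNOCKDOWN), k=1)
        sets = qs.sets["default"]
        assert sets.up == {"g2"} and sets.down == {"g3"}

    def test_covers_only_available_cell_lines(self):
        rng = np.random.default_rng(0)
        sig = make_sigset(
            rng.standard_normal((10, 3)),
            pert_ids=["i", "i", "c"],
            pert_types=[PertType.KNOCKDOWN, PertType.KNOCKDOWN, PertType.COMPOUND],
            target_genes=["g1", "g1", None],
            cell_line=["PC3", "MCF7", "HT29"],
        )
        qs = build_query(sig, Intervention("I", "g1", PertType.KNOCKDOWN), k=2)
        assert set(qs.sets) == {"PC3", "MCF7"}

    def test_absent_intervention_is_excluded_and_logged(self, caplog):
        sig = make_sigset(np.arange(6.0).reshape(-1, 1), **kd("x_kd", "g1"))
        ilist = InterventionList.from_records(
            [("HAVE", "g1", "knockdown"), ("MISS", "g9", "overexpression")]
        )
        with caplog.at_level("INFO", logger="geroscreen.screen"):
            queries, missing = build_queries(sig, ilist, k=1)
        assert [q.intervention_id for q in queries] == ["HAVE"]
        assert missing == ["MISS"]
        assert "no signature available" in caplog.text

    def test_missing_raises_directly(self):
        sig = make_sigset(np.eye(4))
        with pytest.raises(MissingSignatureError):
            build_query(sig, Intervention("I", "g1", PertType.KNOCKDOWN), k=1)

    def test_query_too_large_for_gene_space(self):
        sig = make_sigset(np.arange(4.0).reshape(-1, 1), **kd("i", "g1"))
        with pytest.raises(ValidationError, match="too large"):
            build_query(sig, Intervention("I", "g1", PertType.KNOCKDOWN), k=3)

    def test_consensus_mode_shares_sets_across_lines(self):
        rng = np.random.default_rng(1)
        sig = make_sigset(
            rng.standard_normal((12, 2)),
            pert_ids=["i", "i"],
            pert_types=[PertType.KNOCKDOWN] * 2,
            target_genes=["g1", "g1"],
            cell_line=["PC3", "MCF7"],
        )
        qs = build_query(
            sig, Intervention("I", "g1", PertType.KNOCKDOWN), k=3, mode="consensus"
        )
        assert qs.sets["PC3"] == qs.sets["MCF7"]


class TestScoreCompounds:
    def test_cartesian_row_count(self):
        rng = np.random.default_rng(2)
        sig = make_sigset(
            rng.standard_normal((20, 5)),
            pert_ids=["i1", "i2", "a", "b", "c"],
            pert_types=[PertType.KNOCKDOWN] * 2 + [PertType.COMPOUND] * 3,
            target_genes=["g1", "g2", None, None, None],
        )
        ilist = InterventionList.from_records(
            [("I1", "g1", "knockdown"), ("I2", "g2", "knockdown")]
        )
        queries, _ = build_queries(sig, ilist, k=3)
        table = score_compounds(queries, sig, pert_types=("compound",))
        assert len(table.summary) == 6  # 2 queries x 3 compounds
        assert set(table.summary["pert_id"]) == {"a", "b", "c"}

    def test_self_query_attains_maximum(self, small_universe):
        """A compound queried with its own top/bottom-k scores exactly 100."""
        sigset, _, _, _ = small_universe
        qs = build_self_query(sigset, "CPD0003", k=5)
        table = score_compounds([qs], sigset, pert_types=("compound",))
        row = table.summary[table.summary["pert_id"] == "CPD0003"]
        assert row["summary_score"].tolist() == [100.0]

    def test_reversed_self_query_attains_minimum(self, small_universe):
        sigset, _, _, _ = small_universe
        qs = build_self_query(sigset, "CPD0003", k=5).reversed()
        table = score_compounds([qs], sigset, pert_types=("compound",))
        row = table.summary[table.summary["pert_id"] == "CPD0003"]
        assert row["summary_score"].tolist() == [-100.0]

    def test_zero_signature_compound_scores_zero(self):
        rng = np.random.default_rng(4)
        values = rng.standard_normal((15, 3))
        values[:, 2] = 0.0  # a dead compound
        sig = make_sigset(
            values,
            pert_ids=["i", "a", "dead"],
            pert_types=[PertType.KNOCKDOWN, PertType.COMPOUND, PertType.COMPOUND],
            target_genes=["g1", None, None],
        )
        queries, _ = build_queries(
            sig, InterventionList.from_records([("I", "g1", "knockdown")]), k=3
        )
        table = score_compounds(queries, sig, pert_types=("compound",))
        dead = table.detail[table.detail["pert_id"] == "dead"]
        assert (dead["wtcs"] == 0.0).all()
        row = table.summary[table.summary["pert_id"] == "dead"]
        assert row["summary_score"].tolist() == [0.0]

    def test_no_shared_cell_line_drops_pair(self):
        rng = np.random.default_rng(6)
        sig = make_sigset(
            rng.standard_normal((10, 2)),
            pert_ids=["i", "far"],
            pert_types=[PertType.KNOCKDOWN, PertType.COMPOUND],
            target_genes=["g1", None],
            cell_line=["PC3", "MCF7"],
        )
        queries, _ = build_queries(
            sig, InterventionList.from_records([("I", "g1", "knockdown")]), k=2
        )
        table = score_compounds(queries, sig, pert_types=("compound",))
        assert table.summary.empty


class TestCutoff:
    def test_strict_inequality_at_boundary(self):
        summary = pd.DataFrame(
            {
                "query_id": ["I"] * 3,
                "pert_id": ["a", "b", "c"],
                "pert_type": ["compound"] * 3,
                "target_gene": [""] * 3,
                "summary_score": [95.0, 90.0, 85.0],
            }
        )
        out = apply_cutoff(summary, cutoff=90.0)
        assert out["candidate"].tolist() == [True, False, False]

    def test_extreme_cutoffs(self):
        summary = pd.DataFrame(
            {"query_id": ["I"] * 2, "pert_id": ["a", "b"],
             "summary_score": [100.0, -50.0]}
        )
        assert apply_cutoff(summary, cutoff=-100.0)["candidate"].all()
        assert not apply_cutoff(summary, cutoff=100.0)["candidate"].any()

    def test_cutoff_outside_range_rejected(self):
        with pytest.raises(ValidationError, match="outside"):
            apply_cutoff(pd.DataFrame({"summary_score": []}), cutoff=101.0)


def _summary_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["query_id", "pert_id", "pert_type", "target_gene", "summary_score"],
    )


class TestTargetConcordance:
    def make_inputs(self, kd_score):
        cand = apply_cutoff(
            _summary_frame([("I", "drug", "compound", "", 95.0)]), 90.0
        )
        kd_summary = _summary_frame(
            [("I", "KD_t1", "knockdown", "t1", kd_score)]
        )
        ann = TargetAnnotation({"drug": frozenset({"t1"})})
        return cand, ann, kd_summary

    def test_concordant_target_keeps_hit(self):
        cand, ann, kd_summary = self.make_inputs(92.0)
        hits = target_concordance_filter(cand, ann, kd_summary, 90.0)
        assert hits.matrix.loc["I", "drug"]
        assert hits.provenance["matched_targets"].tolist() == ["t1"]

    def test_discordant_target_removes_hit(self):
        cand, ann, kd_summary = self.make_inputs(50.0)
        hits = target_concordance_filter(cand, ann, kd_summary, 90.0)
        assert not hits.matrix.loc["I", "drug"]

    def test_unannotated_compound_never_hits(self):
        cand, _, kd_summary = self.make_inputs(99.0)
        hits = target_concordance_filter(
            cand, TargetAnnotation({"other": frozenset({"t1"})}), kd_summary, 90.0
        )
        assert not hits.matrix.loc["I", "drug"]

    def test_empty_annotations_warn(self):
        cand, _, kd_summary = self.make_inputs(99.0)
        with pytest.warns(UserWarning, match="empty annotation"):
            hits = target_concordance_filter(cand, TargetAnnotation({}), kd_summary)
        assert not hits.matrix.to_numpy().any()

    def test_filter_only_removes(self, small_universe):
        sigset, annotations, interventions, _ = small_universe
        res = run_screen(sigset, interventions, annotations, cutoff=50.0, k=5)
        prov = res.hits.provenance
        assert (prov["hit"] <= prov["candidate"]).all()


class TestTallyAndRank:
    def test_dense_ranking_with_ties(self):
        matrix = pd.DataFrame(
            np.zeros((12, 4), dtype=bool), columns=["a", "b", "c", "d"]
        )
        for col, n in zip("abcd", (12, 10, 10, 9)):
            matrix.loc[: n - 1, col] = True
        ranking = tally_and_rank(HitMatrix(matrix=matrix, provenance=pd.DataFrame()))
        assert ranking["tally"].tolist() == [12, 10, 10, 9]
        assert ranking["rank"].tolist() == [1, 2, 2, 3]

    def test_empty_matrix_empty_ranking(self):
        ranking = tally_and_rank(
            HitMatrix(matrix=pd.DataFrame(dtype=bool), provenance=pd.DataFrame())
        )
        assert ranking.empty

    def test_zero_tally_excluded_by_default(self):
        matrix = pd.DataFrame({"a": [True], "b": [False]})
        hm = HitMatrix(matrix=matrix, provenance=pd.DataFrame())
        assert tally_and_rank(hm)["pert_id"].tolist() == ["a"]
        assert tally_and_rank(hm, include_zero=True)["pert_id"].tolist() == ["a", "b"]


class TestFullScreen:
    def test_planted_mimic_ranks_first(self, small_universe):
        sigset, annotations, interventions, truth = small_universe
        res = run_screen(sigset, interventions, annotations, cutoff=90.0, k=5)
        # candidate for every mimicked intervention, sole rank-1 compound,
        # and no spurious hits beyond the planted truth
        cand = res.candidates
        plant = cand[cand["pert_id"] == "CPD_MIMIC"]
        assert plant["candidate"].all() and len(plant) == 3
        top = res.ranking.iloc[0]
        assert top["pert_id"] == "CPD_MIMIC" and top["rank"] == 1
        prov = res.hits.provenance
        hit_pairs = set(
            map(tuple, prov.loc[prov["hit"], ["pert_id", "query_id"]].to_numpy())
        )
        truth_pairs = {
            ("CPD_MIMIC", iid) for iid in truth.planted_hits["CPD_MIMIC"]
        }
        assert hit_pairs and hit_pairs <= truth_pairs

    def test_raising_cutoff_never_raises_tallies(self, small_universe):
        sigset, annotations, interventions, _ = small_universe
        prev = None
        for cutoff in (0.0, 50.0, 90.0):
            res = run_screen(
                sigset, interventions, annotations, cutoff=cutoff, k=5,
                include_zero=True,
            )
            tallies = res.ranking.set_index("pert_id")["tally"]
            if prev is not None:
                joined = prev.to_frame("lo").join(tallies.to_frame("hi"), how="outer")
                joined = joined.fillna(0)
                assert (joined["hi"] <= joined["lo"]).all()
            prev = tallies

    def test_determinism_byte_identical(self, small_universe):
        sigset, annotations, interventions, _ = small_universe
        a = run_screen(sigset, interventions, annotations, cutoff=90.0, k=5)
        b = run_screen(sigset, interventions, annotations, cutoff=90.0, k=5)
        assert a.scores.summary.to_csv() == b.scores.summary.to_csv()
        assert a.ranking.to_csv() == b.ranking.to_csv()

    def test_tally_never_exceeds_screened_interventions(self):
        params = SMALL_PARAMS
        sigset, annotations, interventions, _ = simulate_signature_universe(
            params, seed=23
        )
        res = run_screen(sigset, interventions, annotations, cutoff=0.0, k=5,
                         include_zero=True)
        assert (res.ranking["tally"] <= len(interventions)).all()
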