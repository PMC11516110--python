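"""Nearest-neighbour ranking, top-k recovery, EF, AUC and deorphanization."""

import numpy as np
import pytest

from tcrpcdist import (
    GeneratorConfig,
    Repertoire,
    deorphanize,
    enrichment_factor,
    generate_repertoire,
    pairwise_matrix,
    peptide_auc,
    rank_neighbors,
    share_probability_curve,
    topk_success,
)

from conftest import make_record, random_repertoire


@pytest.fixture(scope="module")
def clustered():
    return generate_repertoire(GeneratorConfig(seed=11))


@pytest.fixture(scope="module")
def clustered_matrix(clustered):
    return pairwise_matrix(clustered)


class TestRankNeighbors:
    def test_identical_reference_ranks_first_at_zero(self, rng):
        refs = random_repertoire(rng, 6, peptides=["p1", "p2"])
        query = Repertoire([make_record("q", cdr3a=refs.records[2].cdr["CDR3a"],
                                        cdr3b=refs.records[2].cdr["CDR3b"])])
        ranking = rank_neighbors(query, refs)["q"]
        assert ranking.nearest[0] == refs.records[2].id
        assert ranking.nearest[1] == 0.0

    def test_tied_references_keep_input_order(self):
        twin = dict(cdr3a="CAVSDLEPNSSASKIIF", cdr3b="CASSLTGYGYTF")
        refs = Repertoire([
            make_record("r1", **twin, peptide="p1"),
            make_record("r2", **twin, peptide="p2"),
            make_record("far", cdr3a="CIRSSNTGKLIWGGFKF",
                        cdr3b="CSARDSTGNGYTF", peptide="p3"),
        ])
        query = Repertoire([make_record("q")])
        ranking = rank_neighbors(query, refs)["q"]
        assert [r[0] for r in ranking.neighbors[:2]] == ["r1", "r2"]
        assert ranking.neighbors[0][1] == ranking.neighbors[1][1]

    def test_matches_brute_force_matrix_sort(self, rng):
        rep = random_repertoire(rng, 20, peptides=["a", "b", "c"])
        queries = Repertoire(rep.records[:5], name="q")
        refs = Repertoire(rep.records[5:], name="r")
        rankings = rank_neighbors(queries, refs)
        merged = Repertoire(rep.records, name="all")
        sq = pairwise_matrix(merged).square()
        ids = list(merged.ids)
        for q, ranking in rankings.items():
            qi = ids.index(q)
            expect = sorted(
                (float(sq[qi, ids.index(r.id)]), k) for k, r in enumerate(refs)
            )
            got = [r[0] for r in ranking.neighbors]
            assert got == [refs.records[k].id for _, k in expect]

    def test_empty_reference_set_errors(self):
        with pytest.raises(ValueError, match="empty reference"):
            rank_neighbors(Repertoire([make_record("q")]), Repertoire([]))


class TestTopkSuccess:
    def test_duplicated_pairs_are_perfectly_recovered(self):
        recs = []
        for i, pep in enumerate(["p1", "p2", "p3"]):
            cdr3b = ["CASSEPGYEQYF", "CASSLTGYGYTF", "CSARDSTGNGYTF"][i]
            recs.append(make_record(f"{pep}_a", cdr3b=cdr3b, peptide=pep))
            recs.append(make_record(f"{pep}_b", cdr3b=cdr3b, peptide=pep))
        success, evaluated = topk_success(Repertoire(recs), k=1)
        assert success == 1.0 and evaluated == 1.0

    def test_all_singletons_cannot_succeed(self, rng):
        from tcrpcdist import Specificity

        rep = random_repertoire(rng, 6)
        for i, r in enumerate(rep):
            r.specificity = Specificity(f"unique{i}")
        for k in (1, 2, 5):
            success, _ = topk_success(rep, k=k)
            assert success == 0.0

    def test_monotone_in_k(self, clustered, clustered_matrix):
        fracs = [topk_success(clustered, k=k, matrix=clustered_matrix)[0]
                 for k in (1, 2, 5, 10)]
        assert fracs == sorted(fracs)

    def test_threshold_reports_evaluated_fraction(self, clustered,
                                                  clustered_matrix):
        s_all, f_all = topk_success(clustered, k=10, matrix=clustered_matrix)
        s_thr, f_thr = topk_success(clustered, k=10, threshold=0.15,
                                    matrix=clustered_matrix)
        assert f_thr <= f_all == 1.0
        assert s_thr >= s_all  # evaluated queries are the easy ones


class TestEnrichmentFactor:
    def _ranking(self, refs, order):
        from tcrpcdist.specificity import NeighborRanking
        labels = {r.id: r.label for r in refs}
        return NeighborRanking("q", [(i, 0.1, labels[i]) for i in order])

    def test_single_target_in_45_references_gives_4_5(self):
        # one TPRVTGGGAM-specific TCR in 45, found in the top 10:
        # (1/10) / (1/45) = 4.5
        refs = Repertoire(
            [make_record("hit", peptide="TPRVTGGGAM")]
            + [make_record(f"bg{i}", peptide=f"other{i % 9}") for i in range(44)]
        )
        order = ["hit"] + [f"bg{i}" for i in range(44)]
        ef = enrichment_factor(self._ranking(refs, order), "TPRVTGGGAM", refs)
        assert ef == pytest.approx(4.5)

    def test_uniform_specificity_gives_unity(self):
        refs = Repertoire([make_record(f"r{i}", peptide="p") for i in range(20)])
        order = [f"r{i}" for i in range(20)]
        ef = enrichment_factor(self._ranking(refs, order), "p", refs)
        assert ef == pytest.approx(1.0)

    def test_saturated_top10_at_one_fifth_frequency_gives_5(self):
        refs = Repertoire(
            [make_record(f"hit{i}", peptide="p") for i in range(10)]
            + [make_record(f"bg{i}", peptide=f"o{i}") for i in range(40)]
        )
        order = [f"hit{i}" for i in range(10)] + [f"bg{i}" for i in range(40)]
        ef = enrichment_factor(self._ranking(refs, order), "p", refs)
        assert ef == pytest.approx(5.0)

    def test_absent_specificity_errors_and_missing_from_top_is_zero(self):
        refs = Repertoire([make_record(f"r{i}", peptide="p") for i in range(3)]
                          + [make_record("x", peptide="q")])
        order = [f"r{i}" for i in range(3)] + ["x"]
        ranking = self._ranking(refs, order)
        with pytest.raises(ValueError, match="absent"):
            enrichment_factor(ranking, "nope", refs)
        ranking_short = self._ranking(refs, [f"r{i}" for i in range(3)])
        assert enrichment_factor(ranking_short, "q", refs, top_n=3) == 0.0


class TestShareProbabilityCurve:
    def test_duplicate_pairs_bin_has_probability_one(self):
        rep = Repertoire([
            make_record("a1", peptide="p1"), make_record("a2", peptide="p1"),
            make_record("b1", cdr3a="CIRSSNTGKLIWGGFKF", cdr3b="CSARDSTGNGYTF",
                        peptide="p2"),
            make_record("b2", cdr3a="CIRSSNTGKLIWGGFKF", cdr3b="CSARDSTGNGYTF",
                        peptide="p2"),
        ])
        curve = share_probability_curve(rep, bins=5)
        first = curve.iloc[0]
        assert first["share_probability"] == 1.0

    def test_clustered_zero_bin_beats_base_rate(self, clustered,
                                                clustered_matrix):
        curve = share_probability_curve(clustered, bins=10,
                                        matrix=clustered_matrix)
        base = curve.attrs["base_rate"]
        assert curve.iloc[0]["share_probability"] > base

    def test_random_labels_are_flat_near_base_rate(self, rng):
        # average over reshuffles: the zero-distance bin carries no signal
        rep = random_repertoire(rng, 30)
        from tcrpcdist import Specificity
        labels = [f"p{i % 5}" for i in range(30)]
        mat = pairwise_matrix(rep)
        probs = []
        for _ in range(20):
            shuffled = rng.permutation(labels)
            for r, lab in zip(rep, shuffled):
                r.specificity = Specificity(str(lab))
            curve = share_probability_curve(rep, bins=4, matrix=mat)
            ok = curve.dropna(subset=["share_probability"])
            probs.append(float(
                (ok["share_probability"] * ok["n_pairs"]).sum()
                / ok["n_pairs"].sum()
            ))
        assert np.mean(probs) == pytest.approx(0.2, abs=0.05)

    def test_empty_bins_reported_as_missing(self, clustered, clustered_matrix):
        curve = share_probability_curve(clustered, bins=200,
                                        matrix=clustered_matrix)
        empty = curve[curve["n_pairs"] == 0]
        assert len(empty) > 0
        assert empty["share_probability"].isna().all()


class TestPeptideAuc:
    def test_perfect_separation_gives_auc_one(self):
        tight = dict(cdr3a="CAVSDLEPNSSASKIIF", cdr3b="CASSEPGYEQYF")
        rep = Repertoire(
            [make_record(f"pos{i}", **tight, peptide="TARGET") for i in range(8)]
            + [make_record(f"neg{i}",
                           cdr3a="CIRSSNTGKLIWGGFKF"[:12 + (i % 3)] + "F",
                           cdr3b="CSARDSTGNGYTF", peptide=f"o{i}")
               for i in range(8)]
        )
        mean, sd = peptide_auc(rep, "TARGET", seed=0, allow_small=True)
        assert mean == 1.0

    def test_shuffled_labels_give_half(self, rng):
        cfg = GeneratorConfig(n_specificities=2,
                              tcrs_per_specificity=(15, 15),
                              n_singletons=0, seed=5)
        rep = generate_repertoire(cfg)
        mat = pairwise_matrix(rep)
        from tcrpcdist import Specificity
        labels = [r.label for r in rep]
        aucs = []
        for s in range(20):
            shuffled = rng.permutation(labels)
            for r, lab in zip(rep, shuffled):
                r.specificity = Specificity(str(lab))
            mean, _ = peptide_auc(rep, "PEP01", seed=s, allow_small=True,
                                  matrix=mat)
            aucs.append(mean)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.05)

    def test_min_size_guard(self, clustered):
        with pytest.raises(ValueError, match="allow_small"):
            peptide_auc(clustered, "PEP01")


class TestDeorphanize:
    def test_identical_orphan_called_at_zero(self, rng):
        refs = random_repertoire(rng, 5, peptides=["p1", "p2"])
        orphan = Repertoire([make_record(
            "orph", cdr3a=refs.records[0].cdr["CDR3a"],
            cdr3b=refs.records[0].cdr["CDR3b"])])
        calls = deorphanize(orphan, refs)
        assert calls[0].called and calls[0].distance == 0.0
        assert calls[0].peptide == refs.records[0].label

    def test_distant_orphans_yield_no_calls(self):
        refs = Repertoire([
            make_record("r1", cdr3a="CAVSDLEPNSSASKIIF", cdr3b="CASSEPGYEQYF",
                        peptide="p1"),
            make_record("r2", cdr3a="CAVSDLEPNSSASKIIF", cdr3b="CASSEPGYEQWF",
                        peptide="p1"),
        ])
        orphan = Repertoire([make_record(
            "orph", cdr1a="DSSSTY", cdr2a="IFSNMD", cdr1b="SGDLS",
            cdr2b="YYNGEE", cdr3a="CWWRKHMMWRKHMF", cdr3b="CRKWHDRKWHWWRF")])
        calls = deorphanize(orphan, refs)
        assert not calls[0].called
        assert calls[0].peptide is None and calls[0].distance > 0.15

    def test_threshold_is_strictly_less_than(self):
        refs = Repertoire([
            make_record("r1", peptide="p1"),
            make_record("r2", cdr3a="CIRSSNTGKLIWGGFKF", cdr3b="CSARDSTGNGYTF",
                        peptide="p2"),
        ])
        orphan = Repertoire([make_record("orph")])  # distance 0 to r1
        calls = deorphanize(orphan, refs, call_threshold=0.0)
        assert not calls[0].called  # 0 < 0 is false

    def test_printed_round3_orphans_all_called(self, table4):
        orphans = table4.subset(["r3_01", "r3_03", "r3_05"], name="orphans")
        for r in orphans:
            r.specificity = None
        refs = table4.subset(["r3_02", "r3_04", "r3_06"], name="refs")
        calls = {c.orphan_id: c for c in deorphanize(orphans, refs)}
        assert all(c.called for c in calls.values())
        assert all(c.peptide == "DSNDYHILR" for c in calls.values())
        # the two gene-and-window-sharing pairs sit at exactly zero
        assert calls["r3_01"].distance == 0.0
        assert calls["r3_03"].distance == 0.0
        assert 0.0 < calls["r3_05"].distance < 0.15
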