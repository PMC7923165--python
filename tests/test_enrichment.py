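"""Fisher over-representation scoring, selection rule, clustering, tables."""

import math
from fractions import Fraction

import numpy as np
import pytest

from p2n import datasets as fixtures
from p2n.core import PhosphoTarget, Protein
from p2n.enrichment import (
    cluster_enrichment,
    differential_enrichment,
    enrichment_matrix,
    fisher_enrichment,
    pathway_target_table,
    select_pathways,
)
from p2n.errors import P2NError, ValidationError

from conftest import make_dataset, make_db


def hypergeom_tail(N, K, n, k):
    """Exact upper-tail P(X >= k) by enumeration, in rational arithmetic."""
    total = Fraction(math.comb(N, n))
    acc = Fraction(0)
    for i in range(k, min(K, n) + 1):
        acc += Fraction(math.comb(K, i) * math.comb(N - K, n - i))
    return acc / total


class TestFisher:
    def test_worked_hypergeometric_example(self):
        # N=20, K=4, n=5, k=3: tail = (C(4,3)C(16,2)+C(4,4)C(16,1))/C(20,5)
        db = make_db({"pw": set("ABCDE"), "pad": set("ABCDEFGHIJKLMNOPQRST")})
        ds = make_dataset("x", ["A", "B", "C", "Z"])  # Z outside universe
        ds.add(PhosphoTarget(protein=Protein("F"), direction="up"))
        res = {r.pathway_id: r for r in fisher_enrichment(ds, db)}
        r = res["kegg:pw"]
        assert (r.N, r.K, r.n, r.k) == (20, 4, 5, 3)
        expected = 496 / 15504
        assert r.p == pytest.approx(expected, rel=1e-12)
        assert r.score == pytest.approx(-math.log10(expected))

    def test_zero_overlap_gives_p_one(self):
        db = make_db({"pw": {"A", "B"}, "pad": set("ABCDEFG")})
        ds = make_dataset("x", ["F", "G"])
        res = {r.pathway_id: r for r in fisher_enrichment(ds, db)}
        assert res["kegg:pw"].p == 1.0
        assert res["kegg:pw"].score == 0.0

    def test_pathway_equal_to_universe_is_uninformative(self):
        db = make_db({"pw": set("ABCD")})
        ds = make_dataset("x", ["A", "B"])
        r = fisher_enrichment(ds, db)[0]
        assert r.k == r.K and r.p == 1.0

    def test_empty_target_set_all_p_one(self):
        db = make_db({"pw": {"A", "B"}})
        res = fisher_enrichment(make_dataset("x", []), db)
        assert all(r.p == 1.0 for r in res)

    def test_matches_exact_enumeration_oracle(self):
        """p-values agree with rational-arithmetic tail enumeration on
        random contingency configurations with N <= 60."""
        rng = np.random.default_rng(42)
        for _ in range(300):
            N = int(rng.integers(5, 61))
            n = int(rng.integers(1, N + 1))
            K = int(rng.integers(0, N + 1))
            universe = [f"P{i}" for i in range(N)]
            members = set(rng.choice(universe, size=n, replace=False))
            targets = list(rng.choice(universe, size=K, replace=False))
            db = make_db({"pw": members, "pad": set(universe)})
            ds = make_dataset("x", targets)
            r = {x.pathway_id: x for x in fisher_enrichment(ds, db)}["kegg:pw"]
            expected = hypergeom_tail(N, K, n, r.k)
            assert r.p == pytest.approx(float(expected), rel=1e-10)

    def test_adding_inside_target_never_raises_p(self):
        rng = np.random.default_rng(7)
        universe = [f"P{i}" for i in range(30)]
        members = set(universe[:8])
        db = make_db({"pw": members, "pad": set(universe)})
        targets = list(rng.choice(universe[8:], size=6, replace=False))
        base = {r.pathway_id: r for r in
                fisher_enrichment(make_dataset("x", targets), db)}["kegg:pw"]
        for new in sorted(members):
            grown = {r.pathway_id: r for r in
                     fisher_enrichment(make_dataset("x", targets + [new]), db)}["kegg:pw"]
            assert grown.p <= base.p + 1e-15

    def test_results_sorted_by_p_then_overlap(self):
        db = make_db({"big": set("ABCDEF"), "hit": {"A", "B"}, "pad": set("ABCDEFGHIJ")})
        res = fisher_enrichment(make_dataset("x", ["A", "B"]), db)
        assert [r.p for r in res] == sorted(r.p for r in res)

class TestSelection:
    def test_significant_set_covers_everything(self):
        universe = {f"P{i}" for i in range(40)}
        db = make_db({"sig": {"P0", "P1", "P2"}, "pad": universe})
        ds = make_dataset("x", ["P0", "P1", "P2"])
        res = fisher_enrichment(ds, db)
        sel = select_pathways(res, ds, db)
        assert sel.selected == {"kegg:sig"}
        assert sel.reasons["kegg:sig"] == "significant"
        assert not sel.uncovered

    def test_coverage_rule_adds_nonsignificant_cover(self):
        universe = {f"P{i}" for i in range(60)} | {"a", "b", "c"}
        db = make_db(
            {
                "P1sig": {"a", "b"},
                "P2cover": {"c"} | {f"P{i}" for i in range(20)},
                "P3none": {f"P{i}" for i in range(40, 50)},
                "pad": universe,
            }
        )
        ds = make_dataset("x", ["a", "b", "c"])
        res = fisher_enrichment(ds, db)
        by_id = {r.pathway_id: r for r in res}
        assert by_id["kegg:P1sig"].significant
        assert not by_id["kegg:P2cover"].significant
        sel = select_pathways(res, ds, db)
        assert sel.selected == {"kegg:P1sig", "kegg:P2cover"}
        assert sel.reasons["kegg:P2cover"] == "coverage"

    def test_no_pathway_contains_targets(self):
        db = make_db({"pw": {"A", "B"}}, [("C", "D"), ("E", "F")])
        ds = make_dataset("x", ["E", "F"])
        sel = select_pathways(fisher_enrichment(ds, db), ds, db)
        assert sel.selected == set()
        assert sel.uncovered == {"E", "F"}

    def test_selection_superset_of_significant_and_complete(self):
        rng = np.random.default_rng(3)
        universe = [f"P{i}" for i in range(100)]
        pathways = {
            f"pw{j}": set(rng.choice(universe, size=12, replace=False))
            for j in range(12)
        }
        db = make_db({**pathways, "pad": set(universe)})
        ds = make_dataset("x", list(rng.choice(universe, size=25, replace=False)))
        res = fisher_enrichment(ds, db)
        sel = select_pathways(res, ds, db)
        assert {r.pathway_id for r in res if r.significant} <= sel.selected
        covered = set()
        for pid in sel.selected:
            covered |= db.pathways[pid].members & ds.accessions
        coverable = set()
        for pid in db.pathways:
            coverable |= db.pathways[pid].members & ds.accessions
        assert covered == coverable


class TestDifferential:
    def test_equal_scores_zero_deviation(self):
        per = {}
        db = make_db({"pw": {"A"}, "pad": set("AB")})
        for cond, es in [("c1", 4.0), ("c2", 4.0), ("c3", 4.0)]:
            res = fisher_enrichment(make_dataset(cond, ["A"]), db)
            per[cond] = res
        out = differential_enrichment(per)
        pw = [d for d in out if d.pathway_id == "kegg:pw"][0]
        assert all(abs(v) < 1e-9 for v in pw.deviations.values())

    def test_arithmetic_on_stated_vector(self):
        class R:
            def __init__(self, pid, score):
                self.pathway_id, self.score = pid, score

        per = {"c1": [R("p", 2.0)], "c2": [R("p", 4.0)], "c3": [R("p", 6.0)]}
        out = differential_enrichment(per)[0]
        assert out.mean == pytest.approx(4.0)
        assert out.deviations == pytest.approx({"c1": -2.0, "c2": 0.0, "c3": 2.0})
        assert sum(out.deviations.values()) == pytest.approx(0.0, abs=1e-9)

    def test_missing_condition_scores_zero(self):
        class R:
            def __init__(self, pid, score):
                self.pathway_id, self.score = pid, score

        out = differential_enrichment({"c1": [], "c2": [R("p", 3.0)]})[0]
        assert out.mean == pytest.approx(1.5)
        assert out.deviations["c1"] == pytest.approx(-1.5)

    def test_sorted_by_descending_mean(self):
        class R:
            def __init__(self, pid, score):
                self.pathway_id, self.score = pid, score

        out = differential_enrichment(
            {"c1": [R("lo", 1.0), R("hi", 9.0)], "c2": [R("lo", 1.0), R("hi", 9.0)]}
        )
        assert [d.pathway_id for d in out] == ["hi", "lo"]

    def test_single_condition_rejected(self):
        with pytest.raises(P2NError):
            differential_enrichment({"only": []})


class TestClustering:
    def test_identical_columns_merge_first(self):
        import pandas as pd

        m = pd.DataFrame(
            {"c1": [1.0, 2.0, 3.0], "c2": [1.0, 2.0, 3.0], "c3": [9.0, 0.0, 4.0]},
            index=["p1", "p2", "p3"],
        )
        res = cluster_enrichment(m)
        # c1 and c2 are at distance 0: first merge joins leaves 0 and 1
        assert set(res.col_linkage[0][:2]) == {0.0, 1.0}
        assert res.col_linkage[0][2] == pytest.approx(0.0)

    def test_hand_computed_three_leaf_linkage(self):
        import pandas as pd

        m = pd.DataFrame({"a": [0.0, 1.0, 5.0], "b": [0.0, 1.0, 5.0]}, index=list("xyz"))
        res = cluster_enrichment(m)
        # rows {0},{1} merge first at euclidean height sqrt(2)
        assert set(res.row_linkage[0][:2]) == {0.0, 1.0}
        assert res.row_linkage[0][2] == pytest.approx(np.sqrt(2.0))

    def test_minimal_two_by_two(self):
        import pandas as pd

        m = pd.DataFrame({"a": [0.0, 3.0], "b": [1.0, 2.0]}, index=["p", "q"])
        res = cluster_enrichment(m)
        assert len(res.row_linkage) == 1 and len(res.col_linkage) == 1

    def test_constant_matrix_deterministic(self):
        import pandas as pd

        m = pd.DataFrame(np.ones((3, 3)), index=list("abc"), columns=list("xyz"))
        r1 = cluster_enrichment(m)
        r2 = cluster_enrichment(m)
        assert r1.row_order == r2.row_order and r1.col_order == r2.col_order

    def test_too_small_rejected(self):
        import pandas as pd

        with pytest.raises(ValidationError):
            cluster_enrichment(pd.DataFrame({"a": [1.0]}))


class TestPathwayTargetTable:
    def test_published_bcr_rows(self):
        targets = fixtures.load_example_targets()
        db = fixtures.load_example_db()
        table = pathway_target_table(
            fixtures.BCR_PATHWAY,
            [targets["MCF7"], targets["MDA231"], targets["DG75"]],
            db,
        )
        btk = table[table.accession == "Q06187"].iloc[0]
        assert btk["DG75"] == "551 *"
        assert btk["MCF7"] == "" and btk["MDA231"] == ""
        plcg2 = table[table.accession == "P16885"].iloc[0]
        assert plcg2["MDA231"] == "1217"
        assert plcg2["DG75"] == "550 ; 759 * ; 858 ; 1245"

    def test_published_actin_rows(self):
        targets = fixtures.load_example_targets()
        db = fixtures.load_example_db()
        table = pathway_target_table(
            fixtures.ACTIN_PATHWAY,
            [targets["MCF7"], targets["MDA231"], targets["DG75"]],
            db,
        )
        ezr = table[table.accession == "P15311"].iloc[0]
        assert ezr["MCF7"] == "X"
        assert ezr["MDA231"] == "424"
        # RDX is a pathway member but a target in no dataset: no row
        assert "P35241" not in set(table.accession)

    def test_pathway_without_targets_empty_table(self):
        db = make_db({"pw": {"A", "B"}})
        table = pathway_target_table("kegg:pw", [make_dataset("x", ["Z"])], db)
        assert table.empty

    def test_unknown_pathway_rejected(self):
        db = make_db({"pw": {"A"}})
        with pytest.raises(P2NError):
            pathway_target_table("kegg:nope", [], db)


def test_enrichment_matrix_is_dense_fill_zero():
    db = make_db({"pw": {"A", "B"}, "pw2": {"C"}, "pad": set("ABCDEFGH")})
    per = {
        "c1": fisher_enrichment(make_dataset("c1", ["A", "B"]), db),
        "c2": fisher_enrichment(make_dataset("c2", ["H"]), db),
    }
    m = enrichment_matrix(per)
    assert m.loc["kegg:pw", "c2"] == 0.0
    assert m.loc["kegg:pw", "c1"] > 0.0
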