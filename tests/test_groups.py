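import numpy as np
import pandas as pd
import pytest

from methexpr.groups import (
    assign_groups,
    average_gene_fold_change,
    filter_only_groups,
    members,
    only_members,
    probe_consensus,
    rank_genes,
)
from methexpr.io import ExpressionStatusTable

from conftest import make_annotation


def _results(calls: dict[str, str], deltas: dict[str, float] | None = None,
             cohort="X", pvals: dict[str, float] | None = None):
    probes = sorted(calls)
    return pd.DataFrame(
        {
            "probe_id": probes,
            "cohort": cohort,
            "delta_beta": [(deltas or {}).get(p, 0.1) for p in probes],
            "p_value": [(pvals or {}).get(p, 0.01) for p in probes],
            "adj_p": np.nan,
            "call": [calls[p] for p in probes],
            "n_cancer": 10,
            "n_normal": 10,
        }
    )


def _expr(statuses: dict[str, str]):
    rows = []
    for gene, st in statuses.items():
        lfc = {"UP": 1.0, "DOWN": -1.0, "NS": 0.0}[st]
        rows.append({"gene": gene, "logFC": lfc, "p_value": 0.01 if st != "NS" else 0.5,
                     "status": st})
    return ExpressionStatusTable(pd.DataFrame(rows))


class TestProbeConsensus:
    def test_hyper_in_all_three_cohorts_is_consensus_hyper(self):
        tables = {c: _results({"cg1": "HYPER"}, cohort=c) for c in "ABC"}
        cons = probe_consensus(tables, ["A", "B", "C"])
        assert cons.loc[0, "consensus"] == "HYPER"

    def test_hyper_in_two_ns_in_one_is_none(self):
        tables = {
            "A": _results({"cg1": "HYPER"}, cohort="A"),
            "B": _results({"cg1": "HYPER"}, cohort="B"),
            "C": _results({"cg1": "NS"}, cohort="C"),
        }
        cons = probe_consensus(tables, ["A", "B", "C"])
        assert cons.loc[0, "consensus"] == "NONE"

    def test_conflicting_directions_are_none(self):
        tables = {
            "A": _results({"cg1": "HYPER"}, cohort="A"),
            "B": _results({"cg1": "HYPO"}, cohort="B"),
        }
        cons = probe_consensus(tables, ["A", "B"])
        assert cons.loc[0, "consensus"] == "NONE"

    def test_untestable_in_required_cohort_is_none(self):
        tables = {
            "A": _results({"cg1": "HYPER", "cg2": "HYPER"}, cohort="A"),
            "B": _results({"cg1": "HYPER"}, cohort="B"),  # cg2 missing
        }
        cons = probe_consensus(tables, ["A", "B"]).set_index("probe_id")
        assert cons.loc["cg1", "consensus"] == "HYPER"
        assert cons.loc["cg2", "consensus"] == "NONE"

    def test_mean_delta_averages_over_testable_cohorts(self):
        tables = {
            "A": _results({"cg1": "HYPER"}, deltas={"cg1": 0.1}, cohort="A"),
            "B": _results({"cg1": "HYPER"}, deltas={"cg1": 0.3}, cohort="B"),
        }
        cons = probe_consensus(tables, ["A", "B"])
        assert cons.loc[0, "mean_delta_beta"] == pytest.approx(0.2)

    def test_adding_a_cohort_only_shrinks_consensus_sets(self, rng):
        # consensus monotonicity over random call tables
        probes = [f"cg{i}" for i in range(60)]
        calls_a = {p: rng.choice(["HYPER", "HYPO", "NS"]) for p in probes}
        calls_b = {p: rng.choice(["HYPER", "HYPO", "NS"]) for p in probes}
        calls_c = {p: rng.choice(["HYPER", "HYPO", "NS"]) for p in probes}
        two = probe_consensus(
            {"A": _results(calls_a, cohort="A"), "B": _results(calls_b, cohort="B")},
            ["A", "B"])
        three = probe_consensus(
            {"A": _results(calls_a, cohort="A"), "B": _results(calls_b, cohort="B"),
             "C": _results(calls_c, cohort="C")},
            ["A", "B", "C"])
        for direction in ("HYPER", "HYPO"):
            s2 = set(two.loc[two["consensus"] == direction, "probe_id"])
            s3 = set(three.loc[three["consensus"] == direction, "probe_id"])
            assert s3 <= s2

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            probe_consensus({}, [])


ANN = make_annotation([
    ("cg1", "chr1", 100, "GA", "Island", True, True),
    ("cg2", "chr1", 200, "GA", "None", True, True),
    ("cg3", "chr1", 300, "GB", "None", True, True),
    ("cg4", "chr1", 400, "GB", "None", True, True),
    ("cg5", "chr1", 500, "GC", "None", True, True),
])


def _consensus(mapping):
    return pd.DataFrame(
        {"probe_id": sorted(mapping), "consensus": [mapping[p] for p in sorted(mapping)],
         "mean_delta_beta": 0.1, "n_testable": 3, "calls": ""})


class TestAssignGroups:
    def test_two_hyper_probes_expr_up_is_upup(self):
        cons = _consensus({"cg1": "HYPER", "cg2": "HYPER"})
        out = assign_groups(cons, ANN, _expr({"GA": "UP"}))
        row = out.set_index("gene").loc["GA"]
        assert row["memberships"] == "UPUP"
        assert not row["inconsistent"]

    def test_mixed_directions_expr_up_is_upup_and_downup_flagged(self):
        cons = _consensus({"cg1": "HYPER", "cg2": "HYPO"})
        out = assign_groups(cons, ANN, _expr({"GA": "UP"}))
        row = out.set_index("gene").loc["GA"]
        assert row["memberships"] == "UPUP,DOWNUP"
        assert row["inconsistent"]
        assert row["meth_status"] == "BOTH"

    def test_all_none_probes_give_empty_membership(self):
        cons = _consensus({"cg3": "NONE", "cg4": "NONE"})
        out = assign_groups(cons, ANN, _expr({"GB": "UP"}))
        assert out.set_index("gene").loc["GB", "memberships"] == ""

    def test_expr_ns_gives_empty_membership(self):
        cons = _consensus({"cg1": "HYPER", "cg2": "HYPER"})
        out = assign_groups(cons, ANN, _expr({"GA": "NS"}))
        assert out.set_index("gene").loc["GA", "memberships"] == ""

    def test_gene_without_expression_record_is_empty_membership(self):
        cons = _consensus({"cg5": "HYPER"})
        out = assign_groups(cons, ANN, _expr({"GA": "UP"}))  # no GC record
        assert out.set_index("gene").loc["GC", "memberships"] == ""


class TestAverageFoldChange:
    def test_single_probe_three_cohorts(self):
        tables = {
            c: _results({"cg1": "HYPER"}, deltas={"cg1": d}, cohort=c)
            for c, d in zip("ABC", (0.1, 0.2, 0.3))
        }
        avg = average_gene_fold_change(tables, ANN)
        assert avg["GA"] == pytest.approx(0.2)

    def test_two_probes_equal_deltas(self):
        tables = {"A": _results({"cg1": "HYPER", "cg2": "NS"},
                                deltas={"cg1": 0.15, "cg2": 0.15}, cohort="A")}
        avg = average_gene_fold_change(tables, ANN)
        assert avg["GA"] == pytest.approx(0.15)

    def test_matches_brute_force_on_toy_fixture(self):
        # 3 genes x <=3 probes across 2 cohorts, incl. non-significant probes
        deltas_a = {"cg1": 0.1, "cg2": -0.05, "cg3": 0.2, "cg5": 0.0}
        deltas_b = {"cg1": 0.3, "cg3": 0.1, "cg4": 0.4}
        tables = {
            "A": _results({p: "NS" for p in deltas_a}, deltas=deltas_a, cohort="A"),
            "B": _results({p: "NS" for p in deltas_b}, deltas=deltas_b, cohort="B"),
        }
        gene_of = {"cg1": "GA", "cg2": "GA", "cg3": "GB", "cg4": "GB", "cg5": "GC"}
        sums, counts = {}, {}
        for deltas in (deltas_a, deltas_b):
            for p, d in deltas.items():
                g = gene_of[p]
                sums[g] = sums.get(g, 0.0) + d
                counts[g] = counts.get(g, 0) + 1
        avg = average_gene_fold_change(tables, ANN)
        for g in sums:
            assert avg[g] == pytest.approx(sums[g] / counts[g]), g


def _group_table(rows):
    return pd.DataFrame(
        rows,
        columns=["gene", "meth_status", "expr_status", "memberships",
                 "inconsistent", "avg_delta_beta", "n_hyper", "n_hypo", "n_nondiff"],
    )


class TestOnlyFilter:
    def _groups(self):
        return _group_table([
            {"gene": "GA", "meth_status": "UP", "expr_status": "UP",
             "memberships": "UPUP", "inconsistent": False, "avg_delta_beta": 0.2,
             "n_hyper": 2, "n_hypo": 0, "n_nondiff": 0},
            {"gene": "GB", "meth_status": "UP", "expr_status": "UP",
             "memberships": "UPUP", "inconsistent": False, "avg_delta_beta": 0.2,
             "n_hyper": 2, "n_hypo": 0, "n_nondiff": 0},
            {"gene": "GC", "meth_status": "UP", "expr_status": "UP",
             "memberships": "UPUP", "inconsistent": False, "avg_delta_beta": 0.2,
             "n_hyper": 1, "n_hypo": 0, "n_nondiff": 0},
        ])

    def test_hyper_plus_ns_probes_is_only(self):
        dense = _results({"cg1": "HYPER", "cg2": "NS"})
        out = filter_only_groups(self._groups().iloc[[0]], dense, ANN)
        assert out.loc[0, "status"] == "only"

    def test_any_hypo_probe_excludes(self):
        dense = _results({"cg1": "HYPER", "cg2": "HYPO"})
        out = filter_only_groups(self._groups().iloc[[0]], dense, ANN)
        assert out.loc[0, "status"] == "excluded_hypo"

    def test_no_hyper_probe_excludes(self):
        dense = _results({"cg1": "NS", "cg2": "NS"})
        out = filter_only_groups(self._groups().iloc[[0]], dense, ANN)
        assert out.loc[0, "status"] == "excluded_no_hyper"

    def test_no_dense_probe_excluded_separately(self):
        dense = _results({"cg1": "HYPER", "cg2": "NS"})  # GC's cg5 absent
        out = filter_only_groups(self._groups(), dense, ANN)
        by = out.set_index("gene")["status"]
        assert by["GC"] == "excluded_no_probes"

    def test_partition_accounting_identity(self, small_dataset):
        from methexpr.diffmeth import run_cohort

        ds = small_dataset
        results = {n: run_cohort(b, s) for n, (b, s) in ds.cohorts.items()}
        cons = probe_consensus(results, list(ds.cohorts))
        groups = assign_groups(cons, ds.annotation, ds.expression_status,
                               results_by_cohort=results)
        only = filter_only_groups(groups, results["C"], ds.annotation)
        for base in ("UPUP", "UPDOWN"):
            sub = only.loc[only["base_group"] == base]
            n_status = sub["status"].value_counts()
            assert (n_status.get("only", 0) + n_status.get("excluded_hypo", 0)
                    + n_status.get("excluded_no_hyper", 0)
                    + n_status.get("excluded_no_probes", 0)) == len(members(groups, base))

    def test_planted_inconsistent_genes_flagged_and_filtered(self):
        from methexpr.diffmeth import run_cohort
        from methexpr.simulate import CohortSpec, SimConfig, simulate_dataset

        cfg = SimConfig(
            seed=21, n_genes=60, probes_per_gene_sparse=2, probes_per_gene_dense=6,
            cohorts=[CohortSpec("D", 40, 40, "dense")], beta_noise_sd=0.25,
            group_fractions={"UPUP": 0.5, "UPDOWN": 0.5, "DOWNUP": 0,
                             "DOWNDOWN": 0, "NULL": 0},
            frac_inconsistent=0.4,
        )
        ds = simulate_dataset(cfg)
        res = run_cohort(*ds.cohorts["D"])
        cons = probe_consensus({"D": res}, ["D"])
        groups = assign_groups(cons, ds.annotation, ds.expression_status,
                               results_by_cohort={"D": res})
        flipped = set(
            ds.truth.probes.loc[
                ds.truth.probes.groupby("gene")["direction"].transform("nunique") > 1,
                "gene"]
        )
        assert len(flipped) == 24
        flagged = set(groups.loc[groups["inconsistent"], "gene"])
        # every planted-opposite gene whose both directions reached consensus
        for gene in flipped:
            sub = cons.merge(ds.annotation.associations, on="probe_id")
            sub = sub.loc[sub["gene"] == gene, "consensus"]
            if {"HYPER", "HYPO"} <= set(sub):
                assert gene in flagged

    def test_planted_dense_hypo_probes_always_exclude(self):
        from methexpr.diffmeth import run_cohort
        from methexpr.simulate import CohortSpec, SimConfig, simulate_dataset

        cfg = SimConfig(
            seed=33, n_genes=50, probes_per_gene_sparse=2, probes_per_gene_dense=8,
            cohorts=[CohortSpec("S", 30, 30, "sparse"), CohortSpec("D", 40, 40, "dense")],
            beta_noise_sd=0.25,
            group_fractions={"UPUP": 0.5, "UPDOWN": 0.5, "DOWNUP": 0,
                             "DOWNDOWN": 0, "NULL": 0},
            frac_inconsistent=1.0,  # every gene gets one dense HYPO probe
        )
        ds = simulate_dataset(cfg)
        results = {n: run_cohort(b, s) for n, (b, s) in ds.cohorts.items()}
        cons = probe_consensus({"S": results["S"]}, ["S"])
        groups = assign_groups(cons, ds.annotation, ds.expression_status,
                               results_by_cohort={"S": results["S"]})
        only = filter_only_groups(groups, results["D"], ds.annotation)
        assert len(only) == 50
        assert (only["status"] == "excluded_hypo").all()


class TestRankGenes:
    def _fixture(self):
        calls = {"cg1": "HYPER", "cg2": "HYPER", "cg3": "HYPER", "cg4": "NS",
                 "cg5": "HYPER"}
        pvals = {"cg1": 0.001, "cg2": 0.003, "cg3": 0.004, "cg4": 0.9,
                 "cg5": 0.002}
        return _results(calls, pvals=pvals)

    def test_lower_mean_p_ranks_first(self):
        out = rank_genes(self._fixture(), ANN, ["GA", "GB"], k=2)
        # GA: mean(.001,.003)=.002 < GB: mean(.004)=.004
        assert list(out["gene"]) == ["GA", "GB"]
        assert out.loc[0, "avg_p"] == pytest.approx(0.002)

    def test_ties_break_lexicographically(self):
        calls = {"cg1": "HYPER", "cg3": "HYPER"}
        pvals = {"cg1": 0.01, "cg3": 0.01}
        out = rank_genes(_results(calls, pvals=pvals), ANN, ["GB", "GA"], k=2)
        assert list(out["gene"]) == ["GA", "GB"]

    def test_k_larger_than_group_returns_all(self):
        out = rank_genes(self._fixture(), ANN, ["GA"], k=10)
        assert len(out) == 1

    def test_matches_brute_force_on_five_gene_fixture(self, rng):
        genes = [f"R{i}" for i in range(5)]
        rows = []
        ann_rows = []
        pid = 0
        expected = {}
        for g in genes:
            ps = rng.uniform(1e-4, 0.04, size=int(rng.integers(1, 4)))
            expected[g] = float(np.mean(ps))
            for p in ps:
                rows.append((f"x{pid}", "HYPER", float(p)))
                ann_rows.append((f"x{pid}", "chr1", pid, g, "None", True, True))
                pid += 1
        res = _results({r[0]: r[1] for r in rows},
                       pvals={r[0]: r[2] for r in rows})
        ann = make_annotation(ann_rows)
        out = rank_genes(res, ann, genes, k=5)
        brute = sorted(genes, key=lambda g: (expected[g], g))
        assert list(out["gene"]) == brute

    def test_empty_gene_set_rejected(self):
        with pytest.raises(ValueError):
            rank_genes(self._fixture(), ANN, [], k=3)
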