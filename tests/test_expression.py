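import numpy as np
import pandas as pd
import pytest

from oracles import reachable_reactions
from switchfba.dynamic import FluxTimeSeries
from switchfba.errors import DataError
from switchfba.expression import (
    ExpressionMatrix,
    classify,
    correlate,
    essential_expression_summary,
    essential_genes,
    match_genes,
    read_expression,
    write_expression,
    zero_flux_genes,
)


def make_flux_ts(profiles: dict[str, list[float]], times=None) -> FluxTimeSeries:
    times = np.array(times if times is not None else
                     range(len(next(iter(profiles.values())))), dtype=float)
    fm = pd.DataFrame(profiles, index=[f"t{t}" for t in times]).T
    fm.columns = times
    return FluxTimeSeries(
        times=times,
        flux_matrix=fm,
        growth_curve=pd.Series(np.nan, index=times),
        statuses=["optimal"] * len(times),
    )


def make_expr(rows: dict[str, list[float]], times=None, controls=()) -> ExpressionMatrix:
    times = list(times if times is not None else
                 range(len(next(iter(rows.values())))))
    return ExpressionMatrix(
        values=pd.DataFrame(rows, index=[float(t) for t in times]).T,
        control_rows=set(controls),
    )


class TestReadExpression:
    def test_tsv_roundtrip(self, tmp_path):
        expr = make_expr({"g1": [1, 2, 3, 4], "g2": [4, 3, 2, 1],
                          "g3": [0, 0, 1, 1]}, times=[20, 21, 22, 23])
        path = tmp_path / "expr.tsv"
        write_expression(expr, path)
        back = read_expression(path)
        pd.testing.assert_frame_equal(expr.values, back.values,
                                      check_names=False)

    def test_header_time_parsing(self, tmp_path):
        path = tmp_path / "e.tsv"
        path.write_text("gene\tt20\t21h\n g1\t1.5\t2.5\n".replace(" ", ""))
        expr = read_expression(path)
        assert list(expr.times) == [20.0, 21.0]

    def test_non_numeric_cell_located(self, tmp_path):
        path = tmp_path / "e.tsv"
        path.write_text("gene\tt20\tt21\ng1\t1.5\toops\n")
        with pytest.raises(DataError, match="g1.*t21"):
            read_expression(path)

    def test_duplicate_gene_rejected(self, tmp_path):
        path = tmp_path / "e.tsv"
        path.write_text("gene\tt20\ng1\t1\ng1\t2\n")
        with pytest.raises(DataError, match="duplicate"):
            read_expression(path)


class TestMatchGenes:
    def test_max_mean_abs_flux_wins_and_ties_lexicographic(self, bundle):
        matching = match_genes(bundle.model, bundle.flux_ts)
        mean_abs = bundle.flux_ts.flux_matrix.abs().mean(axis=1)
        g2r = {}
        for rxn in bundle.model.reactions:
            for g in rxn.genes:
                g2r.setdefault(g, []).append(rxn.id)
        for gene, rxns in g2r.items():
            best = sorted(rxns, key=lambda r: (-mean_abs[r], r))[0]
            assert matching[gene] == best

    def test_isozymes_share_reaction(self):
        from switchfba.model import MetabolicModel, Metabolite, Reaction

        m = MetabolicModel(
            metabolites=[Metabolite("A")],
            reactions=[Reaction("R", {"A": -1}, -5, 5,
                                gene_association="iso1 or iso2")],
            objective={"R": 1},
        )
        ts = make_flux_ts({"R": [1, 2, 3]})
        assert match_genes(m, ts) == {"iso1": "R", "iso2": "R"}


class TestCorrelate:
    def test_affine_transform_gives_r_one(self):
        ts = make_flux_ts({"R": [1, 2, 3, 5]})
        expr = make_expr({"g": [3 * v + 7 for v in [1, 2, 3, 5]]})
        rep = correlate(ts, expr, {"g": "R"})
        assert rep.profile("g").r == pytest.approx(1.0)

    def test_sign_flip_gives_minus_one(self):
        ts = make_flux_ts({"R": [1, 2, 3, 5]})
        expr = make_expr({"g": [-1, -2, -3, -5]})
        assert correlate(ts, expr, {"g": "R"}).profile("g").r == pytest.approx(-1.0)

    def test_constant_and_zero_flux_excluded(self):
        ts = make_flux_ts({"RC": [2, 2, 2, 2], "RZ": [0, 0, 0, 0],
                           "RV": [1, 2, 3, 4]})
        expr = make_expr({"gc": [1, 2, 3, 4], "gz": [1, 2, 3, 4],
                          "gv": [1, 2, 3, 4], "gflat": [5, 5, 5, 5]})
        rep = correlate(ts, expr, {"gc": "RC", "gz": "RZ", "gv": "RV",
                                   "gflat": "RV"})
        assert rep.profile("gc").excluded == "constant_flux"
        assert rep.profile("gz").excluded == "zero_flux"
        assert rep.profile("gflat").excluded == "constant_expression"
        assert rep.profile("gv").r == pytest.approx(1.0)
        counts = classify(rep)
        assert counts.n_excluded == 3 and counts.n_classified == 1

    def test_no_overlapping_times_rejected(self):
        ts = make_flux_ts({"R": [1, 2]}, times=[0, 1])
        expr = make_expr({"g": [1, 2]}, times=[50, 60])
        with pytest.raises(DataError, match="overlap"):
            correlate(ts, expr, {"g": "R"})

    def test_nearest_neighbour_alignment_within_one_hour(self):
        ts = make_flux_ts({"R": [1, 2, 3, 4]}, times=[20, 21, 22, 23])
        expr = make_expr({"g": [1, 2, 3, 4]}, times=[20.4, 21.4, 22.4, 23.4])
        assert correlate(ts, expr, {"g": "R"}).profile("g").r == pytest.approx(1.0)


class TestClassify:
    @pytest.mark.parametrize(
        "r,expected",
        [(0.6, "correlated"), (-0.6, "anticorrelated"), (0.0, "uncorrelated"),
         (0.5, "uncorrelated"), (-0.5, "uncorrelated")],
    )
    def test_threshold_rules(self, r, expected):
        from switchfba.expression import CorrelationReport, GeneFluxProfile

        base = np.arange(6.0)

        rep = CorrelationReport(
            profiles=[GeneFluxProfile("g", "R", base, base, r=r)]
        )
        classify(rep)
        assert rep.profile("g").cls == expected

    def test_counts_partition_non_excluded(self, bundle):
        from switchfba.expression import correlate as corr

        rep = corr(bundle.flux_ts, bundle.expression, bundle.matching)
        counts = classify(rep)
        n_total = len(rep.profiles)
        assert sum(counts.counts.values()) == counts.n_classified
        assert counts.n_classified + counts.n_excluded == n_total


class TestScreens:
    def test_zero_flux_matches_reachability_oracle(self, bundle):
        """Genes on branches unreachable from open exchanges — and only
        those — must be flagged zero-flux."""
        active_possible = reachable_reactions(bundle.model)
        zf = zero_flux_genes(bundle.matching, bundle.flux_ts)
        for gene, rid in bundle.matching.items():
            if rid.startswith(("TR_", "CH_")) and rid not in active_possible:
                assert gene in zf, (gene, rid)
        # every zero-flux gene's matched reaction is structurally blocked or
        # simply unused; blocked ones are exactly the blk branches here
        blocked = {g for g, r in bundle.matching.items()
                   if r in bundle.record.blocked_reactions}
        assert blocked <= zf

    def test_zero_flux_and_essential_disjoint(self, bundle):
        zf = zero_flux_genes(bundle.matching, bundle.flux_ts)
        ess = essential_genes(bundle.matching, bundle.flux_ts)
        assert zf.isdisjoint(ess)
        assert ess <= set(bundle.matching)

    def test_all_constant_expression_equal_medians(self):
        ts = make_flux_ts({"R": [1, 2, 3, 4], "Z": [0, 0, 0, 0]})
        expr = make_expr({"g1": [7, 7, 7, 7], "g2": [7, 7, 7, 7]})
        s = essential_expression_summary(ts, expr, {"g1": "R", "g2": "Z"})
        assert s.medians["essential"] == s.medians["non_essential"] == 7.0
        assert s.medians["controls"] is None  # empty group: undefined, not 0

    def test_shifted_essential_expression_recovered(self, bundle):
        """Generator truth: essential genes' group median sits above the
        controls' floor by construction."""
        s = essential_expression_summary(
            bundle.flux_ts, bundle.expression, bundle.matching
        )
        assert s.essential == set(bundle.truth.index[bundle.truth.essential])
        assert s.medians["controls"] == pytest.approx(4.5, abs=0.2)
        assert s.medians["essential"] > s.medians["controls"] + 1.0

    def test_low_expression_flagging(self):
        ts = make_flux_ts({"R": [1, 2, 3, 4], "R2": [2, 3, 1, 5]})
        expr = make_expr({"hi": [8, 8, 8, 9], "lo": [4, 4, 4, 4]})
        s = essential_expression_summary(ts, expr, {"hi": "R", "lo": "R2"},
                                         low_cutoff=5.0)
        assert s.low_expressed_essential == ["lo"]
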