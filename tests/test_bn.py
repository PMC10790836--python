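"""Network enumeration, node fitting, BIC decomposition and ranking."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import riskbn
from riskbn.bn import (
    BNStructure,
    EvidenceGrades,
    NodeFit,
    enumerate_structures,
    fit_node,
    rank_and_select,
    score_all_structures,
    score_network,
)
from riskbn.design import offset_marginal, ttc_marginal
from riskbn.tweedie import sample_tweedie, tweedie_logpdf


def small_data(n_per_cell=4, seed=0):
    """A tiny indicator table over the 8 observed conditions."""
    rng = np.random.default_rng(seed)
    rows = []
    for ttc, off in riskbn.observed_conditions():
        for _ in range(n_per_cell):
            sa = rng.normal(0.5 - 0.1 * ttc + 0.1 * off, 0.2)
            scr = sample_tweedie(np.exp(-0.5 + 0.8 * sa), 1.5, 1.6, n=1, seed=rng)[0]
            rows.append((ttc, off, sa, scr))
    return pd.DataFrame(rows, columns=["ttc_s", "offset_m", "sa", "scr"])


class TestEnumeration:
    def test_forty_eight_structures_no_duplicates(self):
        structs = enumerate_structures()
        assert len(structs) == 48
        assert len(set(structs)) == 48

    def test_sixteen_without_inter_node_edge(self):
        structs = [s for s in enumerate_structures() if not s.has_inter_edge]
        assert len(structs) == 16

    def test_four_with_no_edge_and_orphan_scr(self):
        structs = [s for s in enumerate_structures()
                   if not s.has_inter_edge and not s.scr_parents]
        assert len(structs) == 4

    def test_cyclic_structure_rejected(self):
        with pytest.raises(ValueError):
            BNStructure(sa_parents=("SCR",), scr_parents=("SA",))

    def test_all_structures_acyclic(self):
        for s in enumerate_structures():
            assert not ("SCR" in s.sa_parents and "SA" in s.scr_parents)


class TestNodeFits:
    def test_gaussian_no_parents_closed_form(self):
        data = pd.DataFrame(
            {"ttc_s": [3.5, 3.5, 3.5], "offset_m": [1.5, 1.5, 1.5],
             "sa": [-1.0, 0.0, 1.0], "scr": [0.0, 1.0, 0.0]}
        )
        fit = fit_node("SA", (), data)
        sd = np.sqrt(2.0 / 3.0)  # MLE
        expected = float(np.sum(sps.norm.logpdf([-1, 0, 1], 0.0, sd)))
        assert fit.params["cells"]["all"]["mean"] == pytest.approx(0.0)
        assert fit.loglik == pytest.approx(expected, rel=1e-12)
        assert fit.n_params == 2

    def test_gaussian_cell_means_recovered_at_zero_noise(self):
        rows = []
        for ttc, off in riskbn.observed_conditions():
            rows += [(ttc, off, 1.0 + ttc, 0.0)] * 3
        data = pd.DataFrame(rows, columns=["ttc_s", "offset_m", "sa", "scr"])
        # per-TTC-cell means equal the generating values exactly
        fit = fit_node("SA", ("TTC",), data)
        for label, cell in fit.params["cells"].items():
            assert cell["mean"] == pytest.approx(1.0 + float(label))

    def test_root_nodes_use_fixed_design_frequencies(self):
        data = small_data()
        fit_ttc = fit_node("TTC", (), data)
        assert fit_ttc.n_params == 0
        probs = ttc_marginal()
        expected = sum(np.log(probs[v]) for v in data.ttc_s)
        assert fit_ttc.loglik == pytest.approx(expected)
        with pytest.raises(ValueError):
            fit_node("TTC", ("Offset",), data)

    def test_tweedie_node_link_slope_recovered(self):
        rng = np.random.default_rng(12)
        n = 640
        sa = rng.normal(0, 1, n)
        scr = sample_tweedie(np.exp(0.2 + 0.8 * sa), 1.0, 1.6, seed=13)
        data = pd.DataFrame({"ttc_s": 3.5, "offset_m": 1.5, "sa": sa, "scr": scr})
        fit = fit_node("SCR", ("SA",), data)
        slope = fit.params["beta"][-1]
        se = fit.params["beta_se"][-1]
        assert abs(slope - 0.8) < 3 * se


class TestScoring:
    def test_bic_arithmetic(self):
        fit = NodeFit(node="SA", family="gaussian", parents=(),
                      loglik=-100.0, n_params=4)
        assert fit.bic(640) == pytest.approx(200 + 4 * np.log(640), abs=1e-9)
        assert fit.bic(640) == pytest.approx(225.846, abs=5e-3)

    def test_decomposed_bic_equals_joint_computation(self):
        """The node-wise BIC sum must equal a direct joint-likelihood BIC
        computed by summing the four conditional log-densities row by row."""
        data = small_data(n_per_cell=4, seed=5)  # 32-row fixture
        n = len(data)
        ttc_p, off_p = ttc_marginal(), offset_marginal()
        for structure in [
            BNStructure((), ()),
            BNStructure(("TTC", "Offset"), ("SA",)),
            BNStructure(("TTC", "SCR"), ("Offset",)),
        ]:
            score = score_network(structure, data)
            # independent joint computation from the fitted node parameters
            joint_ll = 0.0
            for _, row in data.iterrows():
                joint_ll += np.log(ttc_p[row.ttc_s]) + np.log(off_p[row.offset_m])
                joint_ll += _sa_logpdf(score.node_fits["SA"], row, data, structure)
                joint_ll += _scr_logpdf(score.node_fits["SCR"], row, data, structure)
            p_total = sum(f.n_params for f in score.node_fits.values())
            joint_bic = -2 * joint_ll + p_total * np.log(n)
            assert score.total_bic == pytest.approx(joint_bic, abs=1e-8)
            assert score.total_bic == pytest.approx(
                sum(score.node_bics.values()), abs=1e-12
            )

    def test_pure_noise_parent_usually_increases_bic(self):
        worse = 0
        reps = 12
        for r in range(reps):
            rng = np.random.default_rng(100 + r)
            data = small_data(n_per_cell=10, seed=200 + r)
            data["sa"] = rng.normal(size=len(data))  # SA unrelated to factors
            base = score_network(BNStructure((), ()), data).total_bic
            extra = score_network(BNStructure(("TTC",), ()), data).total_bic
            worse += extra > base
        assert worse > reps / 2


def _cell_key(fit, row):
    parts = []
    if "TTC" in fit.parents:
        parts.append(str(row.ttc_s))
    if "Offset" in fit.parents:
        parts.append(str(row.offset_m))
    return "|".join(parts) if parts else "all"


def _sa_logpdf(fit, row, data, structure):
    assert fit.family == "gaussian"
    if "cells" in fit.params:
        cell = fit.params["cells"][_cell_key(fit, row)]
        return float(sps.norm.logpdf(row.sa, cell["mean"], cell["sd"]))
    from riskbn.bn import _cell_labels

    cells = _cell_labels(data, structure.sa_parents)
    dummies = pd.get_dummies(cells, dtype=float)
    x = np.concatenate([dummies.loc[row.name].to_numpy(), [row.scr]])
    coef, sd = np.array(fit.params["coef"]), fit.params["sd"]
    return float(sps.norm.logpdf(row.sa - x @ coef, 0.0, sd))


def _scr_logpdf(fit, row, data, structure):
    assert fit.family == "tweedie"
    from riskbn.bn import _cell_labels

    cells = _cell_labels(data, structure.scr_parents)
    dummies = pd.get_dummies(cells, dtype=float)
    x = dummies.loc[row.name].to_numpy()
    beta = np.array(fit.params["beta"])
    if "SA" in structure.scr_parents:
        x = np.concatenate([x, [row.sa]])
    mu = float(np.exp(x @ beta))
    return float(tweedie_logpdf(row.scr, mu, fit.params["phi"], fit.params["xi"]))


class TestOracleJointForSaRegression:
    def test_sa_with_continuous_parent_loglik_is_gaussian_residual(self):
        data = small_data(n_per_cell=6, seed=9)
        fit = fit_node("SA", ("SCR",), data)
        coef = np.array(fit.params["coef"])
        resid = data.sa.to_numpy() - np.column_stack(
            [np.ones(len(data)), data.scr.to_numpy()]
        ) @ coef
        sd = np.sqrt(np.mean(resid**2))
        expected = np.sum(sps.norm.logpdf(resid, 0, sd))
        assert fit.loglik == pytest.approx(expected, rel=1e-10)
        assert fit.n_params == 3  # intercept, slope, sd


class TestRanking:
    def _mk(self, bics):
        out = []
        for i, b in enumerate(bics):
            s = BNStructure((), ("SA",) if i % 2 else ())
            ns = riskbn.NetworkScore(structure=BNStructure((), ()),
                                     node_fits={}, node_bics={}, total_bic=b, n=10)
            # distinct structures for stable ties
            ns.structure = enumerate_structures()[i]
            out.append(ns)
        return out

    def test_gap_grades(self):
        g = EvidenceGrades()
        assert g.grade(1.5) == "indistinguishable"
        assert g.grade(3.0) == "positive"
        assert g.grade(7.0) == "strong"
        assert g.grade(11.0) == "very strong"

    def test_close_top_pair_flagged_indistinguishable(self):
        rep = rank_and_select(self._mk([100.0, 101.5, 110.0]))
        assert len(rep.indistinguishable) == 2
        assert rep.grades[0] == "indistinguishable"
        assert rep.grades[1] == "strong"

    def test_exact_ties_ordered_by_structure_serialization(self):
        rep1 = rank_and_select(self._mk([50.0, 50.0, 60.0]))
        rep2 = rank_and_select(list(reversed(self._mk([50.0, 50.0, 60.0]))))
        assert [s.structure for s in rep1.scores[:2]] == [
            s.structure for s in rep2.scores[:2]
        ]

    def test_empty_scores_rejected(self):
        with pytest.raises(ValueError):
            rank_and_select([])

    def test_invalid_grades(self):
        with pytest.raises(ValueError):
            EvidenceGrades(thresholds=(6.0, 2.0, 10.0))


class TestRecovery:
    def test_generating_structure_recovered(self, transformed):
        """Exhaustive search on data generated with SA|TTC,Offset Gaussian and
        SCR|SA Tweedie must put the generating structure at (or within 2 BIC
        of) the top."""
        data = transformed.rename(columns={"isa_t": "sa", "nscr_t": "scr"})
        rep = rank_and_select(score_all_structures(data))
        truth = BNStructure(sa_parents=("TTC", "Offset"), scr_parents=("SA",))
        top_bics = {s.structure: s.total_bic for s in rep.indistinguishable}
        assert truth in top_bics or rep.best.structure == truth
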