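import numpy as np
import pandas as pd
import pytest

from metbmikit.mediation import (LINKAGE_FORWARD, LINKAGE_NONE,
                                 LINKAGE_P2M_COMBINED, LINKAGE_P2M_DIRECT,
                                 LINKAGE_P2M_MEDIATED, LINKAGE_REVERSE1,
                                 classify_linkages, mediate,
                                 prefilter_candidates, proportion_mediated,
                                 run_grids)
from metbmikit.stats import bh_adjust


class TestMediate:
    def test_noiseless_exact_values(self):
        x = np.arange(1, 21, dtype=float)
        res = mediate(x, 0.5 * x, 0.8 * 0.5 * x, n_boot=200, seed=0, min_cases=20)
        assert res.acme == pytest.approx(0.40, abs=1e-12)
        assert res.ade == pytest.approx(0.0, abs=1e-12)
        assert res.total_effect == pytest.approx(0.40, abs=1e-12)

    def test_broken_first_path_point_acme_zero(self, rng):
        x = np.arange(40, dtype=float)
        m = np.tile([1.0, 2.0], 20)          # exactly orthogonal-in-effect? no:
        m = m - np.polyval(np.polyfit(x, m, 1), x) + m.mean()   # slope vs x = 0
        y = 2.0 * m
        res = mediate(x, m, y, n_boot=200, seed=0)
        assert res.acme == pytest.approx(0.0, abs=1e-10)

    def test_identity_acme_plus_ade_is_total(self, rng):
        for _ in range(10):
            x = rng.normal(size=100)
            m = 0.3 * x + rng.normal(size=100)
            y = 0.5 * m - 0.2 * x + rng.normal(size=100)
            res = mediate(x, m, y, n_boot=100, seed=1)
            assert res.acme + res.ade == pytest.approx(res.total_effect, abs=1e-8)

    def test_point_estimates_match_plain_ols(self, rng):
        x = rng.normal(size=200)
        m = 0.4 * x + rng.normal(size=200)
        y = 0.7 * m + 0.2 * x + rng.normal(size=200)
        res = mediate(x, m, y, n_boot=100, seed=0)
        a = np.polyfit(x, m, 1)[0]
        D = np.column_stack([np.ones(200), x, m])
        beta, *_ = np.linalg.lstsq(D, y, rcond=None)
        assert res.acme == pytest.approx(a * beta[2], abs=1e-10)
        assert res.ade == pytest.approx(beta[1], abs=1e-10)

    def test_p_value_floor_and_ci_bracket(self, rng):
        x = rng.normal(size=300)
        m = 0.8 * x + 0.3 * rng.normal(size=300)
        y = 0.8 * m + 0.3 * rng.normal(size=300)
        res = mediate(x, m, y, n_boot=500, seed=0)
        assert res.p_acme == pytest.approx(2 / 501)
        assert res.acme_ci[0] <= res.acme <= res.acme_ci[1]

    def test_constant_inputs_fail_and_small_boot_warns(self, rng):
        x = rng.normal(size=50)
        with pytest.raises(ValueError, match="constant"):
            mediate(np.ones(50), x, x, n_boot=100)
        with pytest.warns(UserWarning, match="small"):
            mediate(x, 0.5 * x + rng.normal(size=50), rng.normal(size=50), n_boot=50)

    def test_bootstrap_seeded_reproducible(self, rng):
        x = rng.normal(size=100)
        m = 0.5 * x + rng.normal(size=100)
        y = 0.5 * m + rng.normal(size=100)
        a = mediate(x, m, y, n_boot=300, seed=9)
        b = mediate(x, m, y, n_boot=300, seed=9)
        assert a.acme_ci == b.acme_ci and a.p_acme == b.p_acme


class TestProportionMediated:
    def test_full_mediation_construction(self):
        x = np.linspace(1, 5, 60)
        m = 0.5 * x + np.sin(np.arange(60))      # noisy-ish mediator, fixed
        y = 0.8 * m                               # y exactly through m
        res = mediate(x, m, y, n_boot=300, seed=0)
        pm = proportion_mediated(res)
        assert pm.prop == pytest.approx(1.0, abs=1e-10)

    def test_no_mediation_construction(self):
        x = np.linspace(1, 5, 60)
        m = 0.5 * x + np.sin(np.arange(60))
        y = 0.9 * x                               # y exactly direct
        res = mediate(x, m, y, n_boot=300, seed=0)
        pm = proportion_mediated(res)
        assert pm.prop == pytest.approx(0.0, abs=1e-10)

    def test_planted_proportion_recovered(self, rng):
        n = 5000
        x = rng.normal(size=n)
        m = 0.5 * x + rng.normal(size=n)
        y = 0.8 * m + 0.65 * x + rng.normal(size=n)
        pm = proportion_mediated(mediate(x, m, y, n_boot=500, seed=1))
        assert pm.ci[0] <= 0.4 / 1.05 <= pm.ci[1]
        assert not pm.unstable

    def test_unstable_total_flagged(self, rng):
        n = 200
        x = rng.normal(size=n)
        m = 0.5 * x + rng.normal(size=n)
        y = 0.05 * m - 0.02 * x + rng.normal(size=n)   # total ~ 0
        pm = proportion_mediated(mediate(x, m, y, n_boot=500, seed=2))
        assert pm.unstable


class TestPrefilter:
    def _sets(self, rng, n=500, k=5):
        mk = lambda p, s: pd.DataFrame(rng.normal(size=(n, k)),
                                       columns=[f"{p}{i}" for i in range(k)])
        return mk("sp", 0), mk("mb", 1), mk("ph", 2)

    def test_independent_sets_rarely_retained(self):
        clean = 0
        for s in range(100):
            rng = np.random.default_rng(s)
            A, B, C = self._sets(rng)
            res = prefilter_candidates(A, B, C)
            clean += len(res.triples) == 0
        assert clean >= 95

    def test_planted_triple_retained(self, rng):
        n = 500
        A, B, C = self._sets(rng, n)
        A["sp0"] = rng.normal(size=n)
        B["mb0"] = 0.45 * A["sp0"] + rng.normal(size=n)
        C["ph0"] = 0.45 * B["mb0"] + rng.normal(size=n)
        res = prefilter_candidates(A, B, C)
        assert "sp0" in res.retained["microbiome"]
        assert "mb0" in res.retained["metabolome"]
        assert "ph0" in res.retained["phenotype"]
        assert ("sp0", "mb0", "ph0") in res.triples

    def test_no_op_thresholds_give_full_grid(self, rng):
        A, B, C = self._sets(rng, n=60, k=3)
        res = prefilter_candidates(A, B, C, rho_min=0.0, q_max=1.0)
        assert len(res.triples) == 27


class TestGridsAndLinkage:
    def test_empty_and_single_triple_record_counts(self, rng):
        A = pd.DataFrame({"sp0": rng.normal(size=100)})
        B = pd.DataFrame({"mb0": rng.normal(size=100)})
        C = pd.DataFrame({"ph0": rng.normal(size=100)})
        assert run_grids([], A, B, C, n_boot=100, seed=0).empty
        rec = run_grids([("sp0", "mb0", "ph0")], A, B, C, n_boot=100, seed=0)
        assert len(rec) == 3
        assert set(rec["grid"]) == {"direct", "reverse1", "reverse2"}

    def test_bh_within_grid_matches_hand_step_up(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def _evidence(self, **over):
        base = {"p_acme_direct": 0.5, "fdr_acme_direct": 0.8,
                "p_acme_r1": 0.5, "fdr_acme_r1": 0.8,
                "p_acme_r2": 0.5, "fdr_acme_r2": 0.8,
                "p_ade_r2": 0.5, "fdr_ade_r2": 0.8}
        base.update(over)
        rows = []
        for grid, (pa, fa, pd_, fd) in {
            "direct": (base["p_acme_direct"], base["fdr_acme_direct"], 0.5, np.nan),
            "reverse1": (base["p_acme_r1"], base["fdr_acme_r1"], 0.5, np.nan),
            "reverse2": (base["p_acme_r2"], base["fdr_acme_r2"],
                         base["p_ade_r2"], base["fdr_ade_r2"]),
        }.items():
            rows.append({"exposure": "sp", "mediator": "mb", "outcome": "ph",
                         "grid": grid, "p_acme": pa, "fdr_acme": fa,
                         "p_ade": pd_, "fdr_ade": fd})
        return pd.DataFrame(rows)

    def test_global_null_classifies_none(self):
        table = classify_linkages(self._evidence())
        assert table["linkage_class"].iloc[0] == LINKAGE_NONE

    def test_forward_rule_conjunction(self):
        ev = self._evidence(fdr_acme_direct=0.01, p_acme_direct=0.001,
                            p_ade_r2=0.6)
        table = classify_linkages(ev)
        assert table["linkage_class"].iloc[0] == LINKAGE_FORWARD

    def test_reverse1_rule_conjunction(self):
        ev = self._evidence(fdr_acme_r1=0.01, p_acme_r1=0.001)
        table = classify_linkages(ev)
        assert table["linkage_class"].iloc[0] == LINKAGE_REVERSE1

    def test_phenotype_to_microbiome_subclasses(self):
        combined = classify_linkages(self._evidence(
            fdr_acme_r2=0.01, fdr_ade_r2=0.01))["linkage_class"].iloc[0]
        mediated = classify_linkages(self._evidence(
            fdr_acme_r2=0.01))["linkage_class"].iloc[0]
        direct = classify_linkages(self._evidence(
            fdr_ade_r2=0.01))["linkage_class"].iloc[0]
        assert combined == LINKAGE_P2M_COMBINED
        assert mediated == LINKAGE_P2M_MEDIATED
        assert direct == LINKAGE_P2M_DIRECT

    def test_forward_blocked_by_reverse_evidence(self):
        ev = self._evidence(fdr_acme_direct=0.01, p_acme_r1=0.01)
        assert classify_linkages(ev)["linkage_class"].iloc[0] == LINKAGE_NONE

    def test_missing_grid_fails(self):
        ev = self._evidence()
        with pytest.raises(ValueError, match="missing grid"):
            classify_linkages(ev[ev["grid"] != "reverse2"])

    def test_planted_chain_grid_evidence(self, rng):
        # a Gaussian chain x -> m -> y yields a strongly significant direct
        # ACME and a null reverse2 ADE (y carries no information about x
        # beyond m); the reverse indirect effects are genuinely nonzero for
        # Gaussian chains, which is why the rule conjunction alone cannot
        # orient clean chains (see the linkage-classification docs)
        n = 800
        x = rng.normal(size=n)
        m = 0.5 * x + rng.normal(size=n)
        y = 0.5 * m + rng.normal(size=n)
        rec = run_grids([("sp0", "mb0", "ph0")],
                        pd.DataFrame({"sp0": x}), pd.DataFrame({"mb0": m}),
                        pd.DataFrame({"ph0": y}), n_boot=200, seed=0)
        rec = rec.set_index("grid")
        assert rec.loc["direct", "p_acme"] < 0.01
        assert rec.loc["direct", "acme"] == pytest.approx(0.25, abs=0.08)
        assert rec.loc["reverse2", "p_ade"] > 0.05     # no direct y -> x path
        assert rec.loc["reverse1", "acme"] > 0         # mirror-path indirect effect

    def test_fork_structure_fires_reverse2_rule_only(self, rng):
        # x drives m and y separately (a fork): both forward-grid ACMEs are
        # null, while the reverse2 grid sees both an indirect and a direct
        # path, so the rule set assigns the phenotype->microbiome class —
        # the documented observational limit of the rule conjunctions
        n = 600
        x = rng.normal(size=n)
        m = 0.8 * x + rng.normal(size=n)
        y = 0.5 * x + rng.normal(size=n)
        rec = run_grids([("sp0", "mb0", "ph0")],
                        pd.DataFrame({"sp0": x}), pd.DataFrame({"mb0": m}),
                        pd.DataFrame({"ph0": y}), n_boot=200, seed=3)
        grid = rec.set_index("grid")
        assert grid.loc["direct", "p_acme"] > 0.05
        assert grid.loc["reverse1", "p_acme"] > 0.05
        cls = classify_linkages(rec)["linkage_class"].iloc[0]
        assert cls == LINKAGE_P2M_COMBINED
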