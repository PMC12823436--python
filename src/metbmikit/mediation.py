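"""Bidirectional mediation engine for microbiome-metabolome-phenotype triads.

For each candidate (exposure x, mediator m, outcome y) the linear mediation
model is the pair of ordinary least-squares fits

    m = alpha_0 + a x          (mediator model)
    y = beta_0 + c' x + b m    (outcome model)

giving the unstandardized indirect effect ACME = a * b, the direct effect
ADE = c' and total effect a * b + c' (an exact identity for linear models).
Uncertainty comes from a joint nonparametric case-resampling bootstrap of
both fits with percentile CIs and two-sided bootstrap p-values floored at
2/(n_boot + 1).

Every candidate triple is evaluated in three grids — direct
(microbiome -> metabolite -> phenotype), reverse1 (microbiome -> phenotype
-> metabolite) and reverse2 (phenotype -> metabolite -> microbiome) — with
Benjamini-Hochberg correction of ACME p-values within each grid (and of ADE
p-values within reverse2), and triples are classified into linkage classes
by the rule conjunctions over the three grids.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import derive_seed, logger
from .stats import bh_adjust, pairwise_spearman_matrix

GRIDS = ("direct", "reverse1", "reverse2")

LINKAGE_FORWARD = "microbiome->phenotype via metabolite"
LINKAGE_REVERSE1 = "microbiome->metabolome via phenotype"
LINKAGE_P2M_MEDIATED = "phenotype->microbiome mediated"
LINKAGE_P2M_DIRECT = "phenotype->microbiome direct"
LINKAGE_P2M_COMBINED = "phenotype->microbiome combined"
LINKAGE_NONE = "none"


@dataclass
class MediationResult:
    exposure_id: str
    mediator_id: str
    outcome_id: str
    acme: float
    ade: float
    total_effect: float
    prop_mediated: float
    acme_ci: tuple
    ade_ci: tuple
    p_acme: float
    p_ade: float
    n_boot: int
    n_used: int
    seed: int
    acme_draws: np.ndarray = field(repr=False, default=None)
    ade_draws: np.ndarray = field(repr=False, default=None)
    total_draws: np.ndarray = field(repr=False, default=None)


def _boot_p(draws: np.ndarray, n_boot: int) -> float:
    lo = float(np.mean(draws <= 0))
    hi = float(np.mean(draws >= 0))
    return float(min(max(2 * min(lo, hi), 2 / (n_boot + 1)), 1.0))


def mediate(x, m, y, n_boot: int = 1000, seed: int = 0,
            exposure_id: str = "x", mediator_id: str = "m",
            outcome_id: str = "y", min_cases: int = 30) -> MediationResult:
    """Linear-model mediation of x on y through m with a case-resampling
    bootstrap (both regressions refitted jointly on each resample).

    The bootstrap is vectorized: resample index matrices feed closed-form
    OLS moment solutions, so large grids stay tractable.
    """
    x = np.asarray(x, dtype=float).ravel()
    m = np.asarray(m, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    ok = ~(np.isnan(x) | np.isnan(m) | np.isnan(y))
    x, m, y = x[ok], m[ok], y[ok]
    n = x.size
    if n < min_cases:
        raise ValueError(f"mediate needs >= {min_cases} complete cases, got {n}")
    if np.ptp(x) == 0 or np.ptp(m) == 0:
        raise ValueError("constant exposure or mediator")
    if n_boot < 100:
        warnings.warn(f"n_boot={n_boot} is small; CIs and p-values will be coarse")

    def fit(xv, mv, yv):
        # row-wise closed-form OLS; inputs are (B, n) or (n,) arrays
        xm_ = xv.mean(axis=-1, keepdims=True)
        mm_ = mv.mean(axis=-1, keepdims=True)
        ym_ = yv.mean(axis=-1, keepdims=True)
        xc, mc, yc = xv - xm_, mv - mm_, yv - ym_
        sxx = (xc * xc).sum(axis=-1)
        sxm = (xc * mc).sum(axis=-1)
        smm = (mc * mc).sum(axis=-1)
        sxy = (xc * yc).sum(axis=-1)
        smy = (mc * yc).sum(axis=-1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = sxm / sxx
            det = sxx * smm - sxm**2
            c_prime = (smm * sxy - sxm * smy) / det
            b = (sxx * smy - sxm * sxy) / det
            # deterministic mediator (m an exact linear function of x) makes
            # the outcome design singular; resolve to full mediation: fit b
            # from y ~ m, leaving c' the (zero) residual direct effect
            degenerate = det <= 1e-12 * sxx * smm
            if np.any(degenerate):
                b_fb = smy / smm
                c_fb = (sxy - b_fb * sxm) / sxx
                b = np.where(degenerate, b_fb, b)
                c_prime = np.where(degenerate, c_fb, c_prime)
        return a, b, c_prime

    a0, b0, c0 = fit(x, m, y)
    acme, ade = float(a0 * b0), float(c0)
    total = acme + ade

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    ab, bb, cb = fit(x[idx], m[idx], y[idx])
    acme_d = ab * bb
    ade_d = cb
    bad = ~(np.isfinite(acme_d) & np.isfinite(ade_d))
    if bad.any():
        logger.info("mediate: %d degenerate bootstrap resample(s) dropped", int(bad.sum()))
        acme_d, ade_d = acme_d[~bad], ade_d[~bad]
    total_d = acme_d + ade_d

    return MediationResult(
        exposure_id=exposure_id, mediator_id=mediator_id, outcome_id=outcome_id,
        acme=acme, ade=ade, total_effect=total,
        prop_mediated=float(acme / total) if total != 0 else np.nan,
        acme_ci=(float(np.percentile(acme_d, 2.5)), float(np.percentile(acme_d, 97.5))),
        ade_ci=(float(np.percentile(ade_d, 2.5)), float(np.percentile(ade_d, 97.5))),
        p_acme=_boot_p(acme_d, n_boot), p_ade=_boot_p(ade_d, n_boot),
        n_boot=n_boot, n_used=n, seed=seed,
        acme_draws=acme_d, ade_draws=ade_d, total_draws=total_d,
    )


@dataclass
class ProportionMediated:
    prop: float
    ci: tuple
    unstable: bool
    crossing_fraction: float


def proportion_mediated(result: MediationResult) -> ProportionMediated:
    """ACME / total effect per bootstrap draw; point estimate is the median
    of draws with a percentile CI.

    Flagged unstable when more than 5% of total-effect draws fall on the
    other side of zero (the ratio is then ill-defined).
    """
    if result.total_draws is None:
        raise ValueError("result carries no bootstrap draws")
    total_d = result.total_draws
    crossing = float(min(np.mean(total_d <= 0), np.mean(total_d >= 0)))
    with np.errstate(divide="ignore", invalid="ignore"):
        prop_d = result.acme_draws / total_d
    prop_d = prop_d[np.isfinite(prop_d)]
    return ProportionMediated(
        prop=float(np.median(prop_d)),
        ci=(float(np.percentile(prop_d, 2.5)), float(np.percentile(prop_d, 97.5))),
        unstable=crossing > 0.05,
        crossing_fraction=crossing,
    )


# ---------------------------------------------------------------------------
# candidate pre-filtering
# ---------------------------------------------------------------------------

@dataclass
class PrefilterResult:
    retained: dict             # set name -> list of retained feature ids
    triples: list              # (exposure, mediator, outcome) tuples
    pair_tables: dict          # (set_a, set_b) -> long DataFrame rho/p/q


def prefilter_candidates(set_a: pd.DataFrame, set_b: pd.DataFrame,
                         set_c: pd.DataFrame, rho_min: float = 0.1,
                         q_max: float = 0.05,
                         names=("microbiome", "metabolome", "phenotype")) -> PrefilterResult:
    """Cross-set Spearman screen before mediation.

    BH correction is applied within each set-pair; a feature is retained
    only if it has at least one significant cross-set correlation with
    |rho| >= ``rho_min`` and q < ``q_max``.  Candidate triples are the
    Cartesian grid over the retained features of the three sets.
    """
    sets = dict(zip(names, (set_a, set_b, set_c)))
    sig_partners = {name: False for name in names}
    masks = {name: np.zeros(sets[name].shape[1], dtype=bool) for name in names}
    tables = {}
    for na, nb in itertools.combinations(names, 2):
        rho, p = pairwise_spearman_matrix(sets[na], sets[nb])
        q = bh_adjust(p.to_numpy())
        sig = (np.abs(rho.to_numpy()) >= rho_min) & (q < q_max)
        masks[na] |= sig.any(axis=1)
        masks[nb] |= sig.any(axis=0)
        long = rho.stack().rename("rho").to_frame()
        long["p"] = p.stack()
        long["q"] = q.ravel()
        tables[(na, nb)] = long.reset_index(names=[na, nb])
    retained = {name: [f for f, keep in zip(sets[name].columns, masks[name]) if keep]
                for name in names}
    if any(len(v) == 0 for v in retained.values()):
        warnings.warn("prefilter_candidates: at least one retained set is empty; grid is empty")
        triples = []
    else:
        triples = list(itertools.product(*(retained[name] for name in names)))
    logger.info("prefilter_candidates: retained %s -> %d candidate triples",
                {k: len(v) for k, v in retained.items()}, len(triples))
    return PrefilterResult(retained, triples, tables)


# ---------------------------------------------------------------------------
# three grids and linkage classification
# ---------------------------------------------------------------------------

def _orderings(xv, mv, yv):
    # grid -> (x, m, y) role assignment for one (exposure, mediator, outcome)
    return {
        "direct": (xv, mv, yv),      # microbiome -> metabolite -> phenotype
        "reverse1": (xv, yv, mv),    # microbiome -> phenotype -> metabolite
        "reverse2": (yv, mv, xv),    # phenotype -> metabolite -> microbiome
    }


def run_grids(triples, microbiome: pd.DataFrame, metabolome: pd.DataFrame,
              phenotypes: pd.DataFrame, n_boot: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Evaluate every candidate triple in all three grid orderings.

    Per-grid per-triple bootstrap seeds are derived deterministically from
    the master seed and the triple id.  ACME p-values are BH-corrected
    within each grid; ADE p-values within the reverse2 grid only.  A
    single-triple failure is logged and marked, not fatal.
    """
    rows = []
    for exp_id, med_id, out_id in triples:
        xv = microbiome[exp_id].to_numpy(float)
        mv = metabolome[med_id].to_numpy(float)
        yv = phenotypes[out_id].to_numpy(float)
        for grid, (gx, gm, gy) in _orderings(xv, mv, yv).items():
            row = {"exposure": exp_id, "mediator": med_id, "outcome": out_id,
                   "grid": grid, "status": "ok"}
            try:
                res = mediate(gx, gm, gy, n_boot=n_boot,
                              seed=derive_seed(seed, exp_id, med_id, out_id, grid),
                              exposure_id=exp_id, mediator_id=med_id, outcome_id=out_id)
                row.update(acme=res.acme, ade=res.ade, total=res.total_effect,
                           acme_ci_low=res.acme_ci[0], acme_ci_high=res.acme_ci[1],
                           ade_ci_low=res.ade_ci[0], ade_ci_high=res.ade_ci[1],
                           p_acme=res.p_acme, p_ade=res.p_ade, n_used=res.n_used)
            except ValueError as exc:
                logger.warning("mediation failed for (%s, %s, %s) grid %s: %s",
                               exp_id, med_id, out_id, grid, exc)
                row.update(status=f"failed: {exc}", acme=np.nan, ade=np.nan, total=np.nan,
                           p_acme=np.nan, p_ade=np.nan)
            rows.append(row)
    records = pd.DataFrame(rows)
    if records.empty:
        return records
    records["fdr_acme"] = np.nan
    records["fdr_ade"] = np.nan
    for grid in GRIDS:
        mask = records["grid"] == grid
        if mask.any():
            records.loc[mask, "fdr_acme"] = bh_adjust(records.loc[mask, "p_acme"].to_numpy())
    rev2 = records["grid"] == "reverse2"
    if rev2.any():
        records.loc[rev2, "fdr_ade"] = bh_adjust(records.loc[rev2, "p_ade"].to_numpy())
    return records


def classify_linkages(records: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Rule-based linkage classification from the three-grid evidence.

    Rules (applied in order, mutually exclusive):

    * forward (microbiome -> phenotype via metabolite):
      FDR-ACME(direct) < alpha AND p-ACME(reverse1) > alpha AND
      p-ACME(reverse2) > alpha AND p-ADE(reverse2) > alpha;
    * reverse1 (microbiome -> metabolome via phenotype):
      FDR-ACME(reverse1) < alpha AND p-ACME(direct) > alpha AND
      p-ACME(reverse2) > alpha AND p-ADE(reverse2) > alpha;
    * phenotype -> microbiome: p-ACME(direct) > alpha AND
      p-ACME(reverse1) > alpha AND (FDR-ACME(reverse2) < alpha and/or
      FDR-ADE(reverse2) < alpha), subclassed mediated / direct / combined by
      which branch fires;
    * otherwise none.
    """
    out = []
    for key, grp in records.groupby(["exposure", "mediator", "outcome"], sort=False):
        by_grid = {g: grp[grp["grid"] == g] for g in GRIDS}
        missing = [g for g, sub in by_grid.items() if sub.empty]
        if missing:
            raise ValueError(f"triple {key} is missing grid record(s): {missing}")
        d = {g: by_grid[g].iloc[0] for g in GRIDS}
        fdr_acme_dir = d["direct"]["fdr_acme"]
        fdr_acme_r1 = d["reverse1"]["fdr_acme"]
        fdr_acme_r2 = d["reverse2"]["fdr_acme"]
        fdr_ade_r2 = d["reverse2"]["fdr_ade"]
        p_acme_dir = d["direct"]["p_acme"]
        p_acme_r1 = d["reverse1"]["p_acme"]
        p_acme_r2 = d["reverse2"]["p_acme"]
        p_ade_r2 = d["reverse2"]["p_ade"]

        cls, rule = LINKAGE_NONE, ""
        if (fdr_acme_dir < alpha and p_acme_r1 > alpha
                and p_acme_r2 > alpha and p_ade_r2 > alpha):
            cls = LINKAGE_FORWARD
            rule = ("fdr_acme(direct)<a & p_acme(reverse1)>a & "
                    "p_acme(reverse2)>a & p_ade(reverse2)>a")
        elif (fdr_acme_r1 < alpha and p_acme_dir > alpha
                and p_acme_r2 > alpha and p_ade_r2 > alpha):
            cls = LINKAGE_REVERSE1
            rule = ("fdr_acme(reverse1)<a & p_acme(direct)>a & "
                    "p_acme(reverse2)>a & p_ade(reverse2)>a")
        elif p_acme_dir > alpha and p_acme_r1 > alpha:
            acme_fire = fdr_acme_r2 < alpha
            ade_fire = fdr_ade_r2 < alpha
            if acme_fire and ade_fire:
                cls = LINKAGE_P2M_COMBINED
                rule = "p_acme(direct)>a & p_acme(reverse1)>a & fdr_acme(reverse2)<a & fdr_ade(reverse2)<a"
            elif acme_fire:
                cls = LINKAGE_P2M_MEDIATED
                rule = "p_acme(direct)>a & p_acme(reverse1)>a & fdr_acme(reverse2)<a"
            elif ade_fire:
                cls = LINKAGE_P2M_DIRECT
                rule = "p_acme(direct)>a & p_acme(reverse1)>a & fdr_ade(reverse2)<a"
        out.append({"exposure": key[0], "mediator": key[1], "outcome": key[2],
                    "linkage_class": cls, "rule": rule})
    return pd.DataFrame(out)
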