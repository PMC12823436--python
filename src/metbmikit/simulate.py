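"""Seeded synthetic multi-omics cohort generator with recorded ground truth.

Emulates a middle-aged deep-phenotyping cohort (~1,400 participants, ages
50-65, BMI 18-46 kg/m^2) with a log-scale metabolome whose shared latent
factors drive BMI at a configurable population R^2, a zero-inflated
compositional species table, gut-module and proteome layers, continuous
phenotype columns and binary outcomes from a logistic model.  Every planted
effect (variance explained, mediation path coefficients, outcome log-odds)
is written to a :class:`SyntheticTruth` record so downstream inference can be
verified against known answers; inference stages must never read it.

The metabolome model for the informative block is

    m_j = s_j * (z_bmi + lam * f) + gamma * h_j * d + psi * eps_j

where ``z_bmi`` is standardized BMI, ``f`` a shared nuisance factor
(confounding all informative metabolites identically, which is what bounds
the joint R^2 below 1 while individual correlations stay realistic), ``d`` a
latent metabolic-deviation score orthogonal to BMI, ``s_j`` a random sign and
``eps_j`` idiosyncratic noise.  Given the requested joint R^2 and a
per-metabolite correlation target, ``lam`` and ``psi`` are solved in closed
form so the population R^2 of BMI on the informative block is exact.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import check_rng, derive_seed, logger
from .io import OmicsLayer


@dataclass(frozen=True)
class PlantedTriple:
    """One planted exposure -> mediator -> outcome path (linear, additive)."""

    exposure_id: str
    mediator_id: str
    outcome_id: str
    a: float            # exposure -> mediator
    b: float            # mediator -> outcome
    c_prime: float      # direct exposure -> outcome
    noise_sd_m: float = 1.0
    noise_sd_y: float = 1.0

    def __post_init__(self):
        if self.noise_sd_m < 0 or self.noise_sd_y < 0:
            raise ValueError("noise SDs must be nonnegative")

    @property
    def acme(self) -> float:
        return self.a * self.b

    @property
    def total_effect(self) -> float:
        return self.a * self.b + self.c_prime


@dataclass(frozen=True)
class OutcomeSpec:
    """Binary outcome generated from logit = intercept + b_bmi * z_BMI
    + b_deviation * d, with d the latent metabolic-deviation score."""

    name: str
    intercept: float
    logodds_bmi_per_sd: float
    logodds_deviation_per_sd: float = 0.0


@dataclass
class GeneratorConfig:
    n_samples: int = 1408
    n_metabolites: int = 300
    n_species: int = 150
    n_modules: int = 50
    n_proteins: int = 100
    n_phenotypes: int = 20
    bmi_r2_from_metabolome: float = 0.40
    n_informative_metabolites: int = 267
    metabolite_rho: float = 0.30
    deviation_weight: float = 0.30
    phenotype_bmi_weight: float = 0.0
    mediation_triples: list = field(default_factory=list)
    outcome_specs: list = field(default_factory=lambda: [
        OutcomeSpec("t2d", -2.5, 0.9, 0.4),
        OutcomeSpec("mets", -1.5, 1.0, 0.5),
    ])
    species_prevalence_range: tuple = (0.10, 0.95)
    sequencing_depth_range: tuple = (50_000, 100_000)
    age_range: tuple = (50.0, 65.0)
    bmi_log_mean: float = float(np.log(26.5))
    bmi_log_sd: float = 0.145
    bmi_clip: tuple = (18.0, 46.0)
    seed: int = 0

    def __post_init__(self):
        for name in ("n_samples", "n_metabolites", "n_species", "n_modules", "n_proteins"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0 <= self.bmi_r2_from_metabolome < 1:
            raise ValueError("bmi_r2_from_metabolome must be in [0, 1)")
        lo, hi = self.species_prevalence_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("species_prevalence_range must lie within (0, 1]")
        if self.n_informative_metabolites > self.n_metabolites:
            raise ValueError("n_informative_metabolites cannot exceed n_metabolites")
        dlo, dhi = self.sequencing_depth_range
        if dlo < 1 or dhi < dlo:
            raise ValueError("sequencing_depth_range must be increasing and >= 1")

    @classmethod
    def null(cls, **overrides) -> "GeneratorConfig":
        """A configuration with every planted effect switched off."""
        base = dict(bmi_r2_from_metabolome=0.0, deviation_weight=0.0,
                    phenotype_bmi_weight=0.0, mediation_triples=[],
                    outcome_specs=[OutcomeSpec("null_outcome", -1.5, 0.0, 0.0)])
        base.update(overrides)
        return cls(**base)


@dataclass
class SyntheticTruth:
    seed: int
    planted_r2: float
    population_r2: float
    informative_metabolites: list
    metabolite_signs: dict
    shared_factor_var: float
    idiosyncratic_var: float
    deviation_weight: float
    outcome_logodds: dict
    triples: list = field(default_factory=list)

    def to_json(self, path) -> None:
        payload = dataclasses.asdict(self)
        payload["triples"] = [dataclasses.asdict(t) if not isinstance(t, dict) else t
                              for t in self.triples]
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=float)


def _solve_metabolome_noise(r2: float, rho: float, k: int):
    """Solve shared-factor and idiosyncratic variances for an exact joint R^2.

    With unit signal loading, joint R^2 = k / (psi^2 + k(1 + lam^2)) and the
    per-metabolite correlation with BMI is 1/sqrt(1 + lam^2 + psi^2).  When
    the requested per-metabolite correlation is incompatible with the joint
    R^2 it is adjusted (with a log note) rather than silently violated; a
    configuration admitting no positive-variance solution raises.
    """
    if r2 <= 0:
        return 0.0, 1.0
    if rho**2 >= r2:
        rho = float(np.sqrt(0.95 * r2))
        logger.info("metabolite_rho lowered to %.3f to stay below the joint R^2", rho)
    total_extra = k * (1 - r2) / r2           # psi^2 + k * lam^2
    per_met_extra = 1 / rho**2 - 1            # lam^2 + psi^2 (+ deviation var, folded in later)
    if k > 1:
        lam2 = (total_extra - per_met_extra) / (k - 1)
    else:
        lam2 = 0.0
    if lam2 < 0:
        lam2 = 0.0
    psi2 = per_met_extra - lam2
    if psi2 <= 0:
        psi2 = total_extra - k * lam2
    if psi2 <= 0 or not np.isfinite(lam2) or not np.isfinite(psi2):
        raise ValueError(
            "non-positive-definite implied metabolome covariance for "
            f"bmi_r2_from_metabolome={r2}, metabolite_rho={rho}, "
            f"n_informative_metabolites={k}"
        )
    # re-solve lam2 so the joint R^2 stays exact given the final psi2
    if k > 0:
        lam2 = max((total_extra - psi2) / k, 0.0)
    return float(lam2), float(psi2)


def _population_r2(lam2: float, psi2: float, k: int, r2_requested: float) -> float:
    if r2_requested <= 0:
        return 0.0
    return float(k / (psi2 + k * (1 + lam2)))


def generate_cohort(config: GeneratorConfig):
    """Generate all omics layers, the cohort table and the truth record.

    Returns ``(layers, cohort, truth)`` where ``layers`` maps layer name to
    :class:`OmicsLayer` (metabolome and proteome on log scale, species as
    counts, modules log-scale abundances).  Identical (config, seed) yields
    byte-identical outputs.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    ids = [f"S{i:05d}" for i in range(1, n + 1)]

    # --- demographics -----------------------------------------------------
    sex = np.zeros(n, dtype=int)
    sex[: n // 2] = 1
    rng.shuffle(sex)
    age = rng.uniform(*config.age_range, size=n)
    bmi = np.clip(np.exp(rng.normal(config.bmi_log_mean, config.bmi_log_sd, size=n)),
                  *config.bmi_clip)
    z_bmi = (bmi - bmi.mean()) / bmi.std(ddof=0)
    deviation = rng.normal(size=n)               # latent metabolic-deviation score

    # --- metabolome -------------------------------------------------------
    k = config.n_informative_metabolites
    r2 = config.bmi_r2_from_metabolome
    lam2, psi2 = _solve_metabolome_noise(r2, config.metabolite_rho, k)
    gamma = config.deviation_weight
    met_ids = [f"metab_{j + 1}" for j in range(config.n_metabolites)]
    informative = met_ids[:k] if r2 > 0 else []
    signs = rng.choice([-1.0, 1.0], size=k)
    shared = rng.normal(size=n)
    baseline = rng.normal(10.0, 1.0, size=config.n_metabolites)
    M = np.empty((n, config.n_metabolites))
    alt = np.where(np.arange(k) % 2 == 0, 1.0, -1.0)
    for j in range(config.n_metabolites):
        eps = rng.normal(size=n)
        if r2 > 0 and j < k:
            M[:, j] = (baseline[j]
                       + signs[j] * (z_bmi + np.sqrt(lam2) * shared)
                       + gamma * alt[j] * signs[j] * deviation
                       + np.sqrt(psi2) * eps)
        else:
            M[:, j] = baseline[j] + gamma * deviation * rng.normal(0, 0.3) + eps

    # --- species counts (zero-inflated compositional) ---------------------
    sp_ids = [f"species_{j + 1}" for j in range(config.n_species)]
    prevalence = rng.uniform(*config.species_prevalence_range, size=config.n_species)
    base_log = rng.normal(0.0, 1.5, size=config.n_species)
    log_ab = base_log + rng.normal(0.0, 0.5, size=(n, config.n_species))
    present = rng.random((n, config.n_species)) < prevalence
    rel = np.where(present, np.exp(log_ab), 0.0)
    anchor = int(np.argmax(prevalence))
    empty = rel.sum(axis=1) == 0
    rel[empty, anchor] = np.exp(base_log[anchor])
    depths = rng.integers(config.sequencing_depth_range[0],
                          config.sequencing_depth_range[1] + 1, size=n)
    S = rng.multinomial(depths, rel / rel.sum(axis=1, keepdims=True)).astype(float)

    # --- modules and proteome --------------------------------------------
    mod_ids = [f"module_{j + 1}" for j in range(config.n_modules)]
    mod_factor = rng.normal(size=n)
    Mo = (rng.normal(0.0, 1.0, size=(n, config.n_modules))
          + 0.3 * mod_factor[:, None] * rng.normal(0, 1, size=config.n_modules))
    prot_ids = [f"protein_{j + 1}" for j in range(config.n_proteins)]
    P = rng.normal(5.0, 1.0, size=(n, config.n_proteins))

    # --- cohort table ------------------------------------------------------
    cohort = pd.DataFrame(index=pd.Index(ids, name="sample_id"))
    cohort["age"] = age
    cohort["sex"] = sex
    cohort["BMI"] = bmi
    cohort["whr"] = 0.85 + 0.04 * z_bmi + 0.02 * sex + rng.normal(0, 0.04, size=n)
    cohort["vat_attenuation"] = -90 - 4 * z_bmi - 3 * gamma * deviation + rng.normal(0, 5, size=n)
    cohort["gene_richness"] = np.round(
        5e5 - 3e4 * (0.3 * z_bmi + 0.5 * gamma * deviation) + rng.normal(0, 4e4, size=n)
    ).astype(int)
    for j in range(config.n_phenotypes):
        cohort[f"pheno_{j + 1}"] = (config.phenotype_bmi_weight * z_bmi
                                    + rng.normal(size=n))
    outcome_logodds = {}
    for spec in config.outcome_specs:
        logit = (spec.intercept + spec.logodds_bmi_per_sd * z_bmi
                 + spec.logodds_deviation_per_sd * deviation)
        cohort[spec.name] = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
        outcome_logodds[spec.name] = {
            "intercept": spec.intercept,
            "bmi_per_sd": spec.logodds_bmi_per_sd,
            "deviation_per_sd": spec.logodds_deviation_per_sd,
        }

    layers = {
        "metabolome": OmicsLayer("metabolome", ids, met_ids, M, "log"),
        "species": OmicsLayer("species", ids, sp_ids, S, "counts"),
        "modules": OmicsLayer("modules", ids, mod_ids, Mo, "log"),
        "proteome": OmicsLayer("proteome", ids, prot_ids, P, "log"),
    }
    truth = SyntheticTruth(
        seed=config.seed,
        planted_r2=r2,
        population_r2=_population_r2(lam2, psi2, k, r2),
        informative_metabolites=informative,
        metabolite_signs={m: float(s) for m, s in zip(informative, signs)},
        shared_factor_var=lam2,
        idiosyncratic_var=psi2,
        deviation_weight=gamma,
        outcome_logodds=outcome_logodds,
    )
    if config.mediation_triples:
        layers, cohort, truth = plant_mediation_paths(
            layers, cohort, config.mediation_triples,
            seed=derive_seed(config.seed, "mediation"), truth=truth)
    return layers, cohort, truth


def _resolve_column(layers: dict, cohort: pd.DataFrame, feature_id: str):
    for name, layer in layers.items():
        if feature_id in layer.feature_ids:
            return "layer", name, layer.feature_ids.index(feature_id)
    if feature_id in cohort.columns:
        return "cohort", feature_id, None
    raise KeyError(f"feature id {feature_id!r} not found in any layer or the cohort table")


def plant_mediation_paths(layers: dict, cohort: pd.DataFrame, triples,
                          seed=None, truth: SyntheticTruth | None = None):
    """Overwrite mediator and outcome columns with planted linear paths.

    For each triple, the mediator column becomes a * exposure + noise and the
    outcome column b * mediator + c' * exposure + noise, using the exposure
    column's current values on its stored scale.  Triples sharing a mediator
    (or outcome) column with different generative rules conflict and raise.
    """
    rng = check_rng(seed)
    seen_m, seen_y = {}, {}
    for t in triples:
        if t.mediator_id in seen_m and seen_m[t.mediator_id] != (t.exposure_id, t.a, t.noise_sd_m):
            raise ValueError(f"conflicting triples share mediator {t.mediator_id!r}")
        if t.outcome_id in seen_y:
            raise ValueError(f"conflicting triples share outcome {t.outcome_id!r}")
        seen_m[t.mediator_id] = (t.exposure_id, t.a, t.noise_sd_m)
        seen_y[t.outcome_id] = True

    layers = {name: OmicsLayer(l.layer_name, l.sample_ids, l.feature_ids,
                               l.values.copy(), l.transform_state)
              for name, l in layers.items()}
    cohort = cohort.copy()
    n = len(cohort)

    def read_col(loc):
        kind, name, j = loc
        return layers[name].values[:, j] if kind == "layer" else cohort[name].to_numpy(float)

    def write_col(loc, values):
        kind, name, j = loc
        if kind == "layer":
            layers[name].values[:, j] = values
        else:
            cohort[name] = values

    for t in triples:
        x = read_col(_resolve_column(layers, cohort, t.exposure_id))
        m_loc = _resolve_column(layers, cohort, t.mediator_id)
        y_loc = _resolve_column(layers, cohort, t.outcome_id)
        m = t.a * x + t.noise_sd_m * rng.normal(size=n) if t.noise_sd_m > 0 else t.a * x
        write_col(m_loc, m)
        y = t.b * m + t.c_prime * x
        if t.noise_sd_y > 0:
            y = y + t.noise_sd_y * rng.normal(size=n)
        write_col(y_loc, y)
    if truth is not None:
        truth.triples = list(truth.triples) + [dataclasses.asdict(t) for t in triples]
    return layers, cohort, truth


def generate_gene_count_table(n_samples: int, n_genes: int, depth_range,
                              seed=None) -> OmicsLayer:
    """Nonnegative integer gene count matrix with per-sample totals drawn
    uniformly from ``depth_range`` (inclusive)."""
    lo, hi = int(depth_range[0]), int(depth_range[1])
    if lo < 1 or hi < lo:
        raise ValueError("depth_range must be increasing and >= 1")
    rng = check_rng(seed)
    probs = rng.lognormal(0.0, 1.0, size=n_genes)
    probs /= probs.sum()
    depths = rng.integers(lo, hi + 1, size=n_samples)
    counts = rng.multinomial(depths, np.tile(probs, (n_samples, 1))).astype(float)
    ids = [f"G{i:05d}" for i in range(1, n_samples + 1)]
    genes = [f"gene_{j + 1}" for j in range(n_genes)]
    return OmicsLayer("gene_counts", ids, genes, counts, "counts")
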