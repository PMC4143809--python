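"""Synthetic cohort generator: family-blocked genotypes and longitudinal states.

Genotypes follow Hardy-Weinberg proportions in family founders, with
within-family correlation induced by gene-dropping (each child receives one
allele from each of the two founders).  Longitudinal hypertension states are
generated by the same generalized-logit transition mechanism the pipeline
estimates: the initial state is categorical, and each subsequent state is
multinomial with linear predictors gamma_l,j' [1, sex, smoke, age_c] where
age_c = (age - 50)/10.  Optional causal SNPs shift the predictor of the
hypertensive destination (state 3) by beta * dosage.  Blood-pressure values
are then drawn uniformly inside the assigned state's (SBP, DBP) region so
that state assignment round-trips exactly for non-medication exams; the
generator therefore reproduces the state-assignment geometry of real cohorts
but not their BP autocorrelation or measurement error.

All randomness flows through one ``numpy.random.default_rng`` seeded stream,
so outputs are fully reproducible for a given configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .states import ExamRecord
from . import states as states_mod
from . import transition as transition_mod
from . import dirichlet as dirichlet_mod
from .qc import GenotypeMatrix

#: Default transition coefficients gamma[l][j] for destinations j != l, on
#: covariates (intercept, sex, smoke, age_c); diagonal dominance keeps most
#: subjects in their current state between exams, with age and smoking
#: pushing toward hypertension.
DEFAULT_GAMMA: dict[int, dict[int, tuple[float, float, float, float]]] = {
    1: {2: (-1.0, 0.15, 0.30, 0.35), 3: (-2.2, 0.20, 0.40, 0.50)},
    2: {1: (-0.8, -0.10, -0.20, -0.30), 3: (-1.2, 0.15, 0.35, 0.45)},
    3: {1: (-2.0, -0.10, -0.25, -0.35), 2: (-1.0, -0.10, -0.20, -0.25)},
}

#: (SBP, DBP) sampling rectangles per state; state 2 samples the complement
#: of the state-1 box within its own box by rejection.
BP_BOXES = {
    1: ((90.0, 119.0), (50.0, 79.0)),
    2: ((90.0, 139.0), (50.0, 89.0)),
    3: ((140.0, 180.0), (90.0, 110.0)),
}


@dataclass
class SimulationConfig:
    """Study-condition settings for the synthetic cohort.

    Defaults emulate a GWAS family cohort of about 850 genotyped and
    phenotyped individuals observed at four examinations, nuclear families
    of 4-8 members, and low clinical/genotype missingness.
    """

    n_families: int = 142
    family_sizes: tuple[int, ...] = (4, 5, 6, 7, 8)
    n_exams: int = 4
    n_markers: int = 500
    maf_range: tuple[float, float] = (0.05, 0.5)
    clinical_missing_rate: float = 0.01
    genotype_missing_rate: float = 0.002
    init_probs: tuple[float, float, float] = (0.55, 0.30, 0.15)
    meds_rate: float = 0.3
    gamma: Mapping[int, Mapping[int, Sequence[float]]] = field(
        default_factory=lambda: DEFAULT_GAMMA)
    causal_effects: dict[int, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.clinical_missing_rate, self.genotype_missing_rate,
                  self.meds_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.seed is None:
            raise ValueError("a seed is required for reproducibility")


def _family_layout(cfg: SimulationConfig, rng: np.random.Generator
                   ) -> list[int]:
    sizes = rng.choice(cfg.family_sizes, size=cfg.n_families, replace=True)
    return [int(s) for s in sizes]


def simulate_genotypes(cfg: SimulationConfig,
                       rng: np.random.Generator | None = None,
                       family_sizes: Sequence[int] | None = None
                       ) -> tuple[GenotypeMatrix, list[str]]:
    """Family-blocked genotypes under HWE with gene-dropping.

    Each family has two founders drawn from HWE at the marker's MAF; the
    remaining members are offspring receiving one allele from each founder.
    Returns the genotype matrix plus the per-subject family ids.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    sizes = list(family_sizes) if family_sizes is not None else _family_layout(cfg, rng)
    mafs = rng.uniform(*cfg.maf_range, size=cfg.n_markers)
    sample_ids: list[str] = []
    family_ids: list[str] = []
    rows: list[np.ndarray] = []
    for f, size in enumerate(sizes):
        fam = f"F{f + 1:04d}"
        n_founders = min(2, size)
        founders = rng.binomial(2, mafs, size=(n_founders, cfg.n_markers)).astype(float)
        members = [founders[i] for i in range(n_founders)]
        for _ in range(size - n_founders):
            a1 = rng.binomial(1, founders[0] / 2.0)
            a2 = rng.binomial(1, founders[1] / 2.0)
            members.append((a1 + a2).astype(float))
        for i, g in enumerate(members):
            sample_ids.append(f"{fam}_S{i + 1}")
            family_ids.append(fam)
            rows.append(g)
    dosage = np.stack(rows)
    if cfg.genotype_missing_rate > 0:
        miss = rng.random(dosage.shape) < cfg.genotype_missing_rate
        dosage[miss] = np.nan
    markers = pd.DataFrame({
        "id": [f"snp{k + 1}" for k in range(cfg.n_markers)],
        "chrom": "3",
        "pos": np.arange(1, cfg.n_markers + 1) * 1000,
        "ref": "A",
        "alt": "B",
    })
    return (GenotypeMatrix(samples=sample_ids, markers=markers, dosage=dosage,
                           hard_calls=True), family_ids)


def _transition_probs(state: int, cov: np.ndarray, snp_shift: float,
                      gamma: Mapping[int, Mapping[int, Sequence[float]]]
                      ) -> np.ndarray:
    eta = np.zeros(3)
    for j, g in gamma[state].items():
        eta[j - 1] = float(np.dot(np.asarray(g, float), cov))
    eta[2] += snp_shift  # causal SNPs push toward the hypertensive state
    eta[state - 1] = 0.0
    ex = np.exp(eta - eta.max())
    return ex / ex.sum()


def _draw_bp(state: int, meds: bool, rng: np.random.Generator
             ) -> tuple[float, float]:
    if meds:
        return float(rng.uniform(90, 180)), float(rng.uniform(50, 110))
    (slo, shi), (dlo, dhi) = BP_BOXES[state]
    if state != 2:
        return float(rng.uniform(slo, shi)), float(rng.uniform(dlo, dhi))
    while True:  # complement of the state-1 box within the state-2 box
        sbp = float(rng.uniform(slo, shi))
        dbp = float(rng.uniform(dlo, dhi))
        if sbp >= 120 or dbp >= 80:
            return sbp, dbp


def simulate_phenotypes(cfg: SimulationConfig, genotypes: GenotypeMatrix,
                        family_ids: Sequence[str],
                        rng: np.random.Generator | None = None
                        ) -> tuple[list[ExamRecord], pd.DataFrame]:
    """Longitudinal exam records generated by the transition mechanism.

    Returns the exam records plus a per-subject truth table (latent states
    before missingness, covariates).  Causal-SNP dosages (``cfg.causal_effects``
    maps marker index to effect size) enter the state-3 linear predictor.
    """
    rng = rng or np.random.default_rng(cfg.seed + 1)
    records: list[ExamRecord] = []
    truth_rows = []
    dose = np.nan_to_num(genotypes.dosage, nan=1.0)
    for i, sid in enumerate(genotypes.samples):
        sex = int(rng.random() < 0.5)
        smoke = int(rng.random() < 0.25)
        age0 = float(rng.uniform(20, 70))
        snp_shift = sum(beta * dose[i, k] for k, beta in cfg.causal_effects.items())
        state = int(rng.choice([1, 2, 3], p=cfg.init_probs))
        states_latent = []
        for t in range(1, cfg.n_exams + 1):
            age = age0 + (t - 1) * 4.0
            if t > 1:
                cov = np.array([1.0, sex, smoke, (age - 4.0 - 50.0) / 10.0])
                probs = _transition_probs(state, cov, snp_shift, cfg.gamma)
                state = int(rng.choice([1, 2, 3], p=probs))
            states_latent.append(state)
            meds = bool(state == 3 and rng.random() < cfg.meds_rate)
            sbp, dbp = _draw_bp(state, meds, rng)
            vals = {"sbp": sbp, "dbp": dbp, "meds": meds, "sex": sex,
                    "smoke": smoke, "age": age}
            if cfg.clinical_missing_rate > 0 and rng.random() < cfg.clinical_missing_rate:
                vals[str(rng.choice(["sbp", "dbp", "meds", "age"]))] = None
            records.append(ExamRecord(
                subject_id=sid, family_id=family_ids[i], exam=t,
                sbp=vals["sbp"], dbp=vals["dbp"], meds=vals["meds"],
                sex=vals["sex"], smoke=vals["smoke"], age=vals["age"],
            ))
        truth_rows.append({"subject_id": sid, "family_id": family_ids[i],
                           "sex": sex, "smoke": smoke, "age0": age0,
                           "snp_shift": snp_shift,
                           "states": "".join(map(str, states_latent))})
    return records, pd.DataFrame(truth_rows)


def simulate_cohort(cfg: SimulationConfig
                    ) -> tuple[GenotypeMatrix, list[str], list[ExamRecord], pd.DataFrame]:
    """Genotypes and phenotypes from a single seeded stream."""
    rng = np.random.default_rng(cfg.seed)
    genotypes, family_ids = simulate_genotypes(cfg, rng)
    records, truth = simulate_phenotypes(cfg, genotypes, family_ids, rng)
    return genotypes, family_ids, records, truth


def recovery_study(cfg: SimulationConfig, replicates: int = 10,
                   alpha: float = 0.05, scan_model: str = "M1") -> pd.DataFrame:
    """Repeated full-pipeline runs summarizing test calibration and power.

    Each replicate simulates a cohort, builds responses through the state and
    transition stages, scans every marker with the Dirichlet Wald test, and
    records the rejection rate at ``alpha`` separately for null and causal
    markers.  One summary row per replicate.
    """
    rows = []
    for rep in range(replicates):
        rep_cfg = SimulationConfig(**{**cfg.__dict__, "seed": cfg.seed + rep})
        genotypes, family_ids, records, _ = simulate_cohort(rep_cfg)
        seqs = states_mod.build_state_sequences(records)
        trans_rows = transition_mod.build_transition_rows(seqs)
        fits = transition_mod.fit_transition_models(trans_rows, select_time=False,
                                                   formulas={1: "base", 2: "base", 3: "base"})
        responses = transition_mod.responses_to_frame(
            [transition_mod.extract_response(s, fits) for s in seqs])
        scan = dirichlet_mod.snp_scan(responses, genotypes, models=(scan_model,))
        p = scan[f"p_{scan_model}"].to_numpy(float)
        causal = np.zeros(len(scan), bool)
        causal[list(rep_cfg.causal_effects)] = True
        ok = np.isfinite(p)
        rows.append({
            "replicate": rep,
            "n_subjects": len(responses),
            "n_markers_tested": int(ok.sum()),
            "null_rejection_rate": float(np.mean(p[ok & ~causal] < alpha))
            if np.any(ok & ~causal) else np.nan,
            "causal_rejection_rate": float(np.mean(p[ok & causal] < alpha))
            if np.any(ok & causal) else np.nan,
            "min_p": float(np.nanmin(p)) if ok.any() else np.nan,
        })
    return pd.DataFrame(rows)
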