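"""Synthetic cohorts with the statistical structure the pipeline assumes.

Two generators are provided.

* The **matrix-level** generator builds weighted structural connectomes
  (distance-dependent geometric graphs with heavy-tailed, log-normal weights,
  perturbed per participant around a group template), derives the four
  predictor matrices, and synthesizes condition-specific FC as noisy mixtures
  of region-preferred predictor columns: each region's FC profile follows its
  preferred measure's column, scaled by a regional coupling gradient (high
  "unimodal" vs. low "multimodal" regions), a global condition offset (rest
  highest, one low-coupling task lowest), a rest-specific pattern component,
  and a participant deviation tied to the phenotype in signal regions.

* The **coupling-level** generator plants the same structure directly on the
  r_C table with exact effect sizes: per-region phenotype associations
  (corr(g, r_C) equal to a requested effect_r), exact condition offsets and
  per-participant dispersion, and weak covariate-phenotype confounds.  The
  resampling-heavy calibration studies use this path; the matrix-level path
  is exercised by end-to-end identifiability checks.

The phenotype emulates a standardized general-ability score (reported on a
mean 0.25, SD 0.83 scale, approximately normal).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import squareform, pdist

from .coupling import CouplingTable
from .datatypes import (
    HCP_CONDITIONS,
    MEASURES,
    AnalysisConfig,
    FunctionalConnectome,
    ParticipantTable,
    StructuralConnectome,
    ValidationError,
)
from .io import Cohort
from .measures import all_predictors

__all__ = [
    "SignalSpec",
    "GeneratorConfig",
    "CouplingGenConfig",
    "generate_sc",
    "generate_fc",
    "generate_phenotype",
    "generate_cohort",
    "generate_coupling_cohort",
    "timeseries_for_fc",
]

G_MEAN, G_SD = 0.25, 0.83  # reporting scale of the phenotype score


@dataclass(frozen=True)
class SignalSpec:
    """One planted region x measure x phenotype association.

    ``effect_r`` is the signed target correlation between the phenotype and
    the region's coupling under ``measure``; ``condition`` limits the effect
    to one condition (None = all task conditions, sharing one latent).
    """

    region: int
    measure: str
    effect_r: float
    condition: str | None = None

    def __post_init__(self) -> None:
        if not -1.0 < self.effect_r < 1.0:
            raise ValidationError("effect_r must lie in (-1, 1)")


def _default_confounds() -> dict[str, float]:
    # weak, realistic covariate-phenotype correlations: slight age and motion
    # disadvantages, negligible gender/handedness effects
    return {"age": -0.10, "gender": 0.10, "handedness": 0.0, "motion": -0.15}


def _conditions(n_tasks: int) -> tuple[str, ...]:
    if n_tasks == len(HCP_CONDITIONS) - 1:
        return HCP_CONDITIONS
    return ("RES",) + tuple(f"T{i + 1}" for i in range(n_tasks))


# ---------------------------------------------------------------------------
# matrix-level generator


@dataclass
class GeneratorConfig:
    """Study conditions for the matrix-level cohort generator."""

    n_participants: int = 200
    n_regions: int = 60
    n_task_conditions: int = 7
    density: float = 0.25
    signal_regions: tuple[SignalSpec, ...] = ()
    condition_offsets: dict[str, float] = field(
        default_factory=lambda: {"RES": 0.05, "EMO": -0.05}
    )
    rest_divergence: float = 0.10
    task_jitter_sd: float = 0.045
    noise_sd: float = 1.0
    participant_sd: float = 0.05
    total_signal_r2: float = 0.10
    confound_strengths: dict[str, float] = field(default_factory=_default_confounds)
    coupling_scale: tuple[float, float] = (0.35, 0.85)
    weight_jitter_sd: float = 0.2
    preferred_measure: str | None = None  # uniform override; default = blocks
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.density <= 1.0:
            raise ValidationError("density must lie in (0, 1]")
        self.conditions = _conditions(self.n_task_conditions)

    @property
    def task_conditions(self) -> tuple[str, ...]:
        return self.conditions[1:]


def _template_graph(cfg: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    """Distance-dependent weighted template SC on random unit-cube positions."""
    n = cfg.n_regions
    pos = rng.uniform(size=(n, 3))
    dist = squareform(pdist(pos))
    decay = np.exp(-dist / 0.3)
    iu = np.triu_indices(n, k=1)
    scale = cfg.density * len(iu[0]) / decay[iu].sum()
    prob = np.clip(scale * decay, 0.0, 1.0)
    edges = np.zeros((n, n), dtype=bool)
    edges[iu] = rng.uniform(size=len(iu[0])) < prob[iu]
    if cfg.density * comb(n, 2) < n - 1:
        warnings.warn("requested density cannot connect the graph; "
                      "spanning-tree edges added")
    # guarantee connectedness with the distance minimum spanning tree
    mst = minimum_spanning_tree(csr_matrix(dist)).toarray() > 0
    edges |= mst | mst.T
    edges |= edges.T
    weights = np.zeros((n, n))
    w_iu = rng.lognormal(mean=0.0, sigma=1.0, size=len(iu[0]))
    weights[iu] = np.where(edges[iu], w_iu, 0.0)
    weights += weights.T
    return weights


def generate_sc(
    cfg: GeneratorConfig, rng: np.random.Generator | None = None
) -> list[StructuralConnectome]:
    """Per-participant SCs: multiplicative log-normal jitter on a template."""
    rng = rng or np.random.default_rng(cfg.seed)
    template = _template_graph(cfg, rng)
    n = cfg.n_regions
    iu = np.triu_indices(n, k=1)
    scs = []
    for p in range(cfg.n_participants):
        jitter = np.zeros((n, n))
        jitter[iu] = rng.normal(0.0, cfg.weight_jitter_sd, size=len(iu[0]))
        jitter += jitter.T
        w = template * np.exp(jitter)
        scs.append(StructuralConnectome(f"sub-{p + 1:04d}", w))
    return scs


def _standardize_offdiag(m: np.ndarray) -> np.ndarray:
    off = ~np.eye(m.shape[0], dtype=bool)
    mu, sd = m[off].mean(), m[off].std()
    z = (m - mu) / (sd if sd > 0 else 1.0)
    np.fill_diagonal(z, 0.0)
    return z


def _preferred_measures(cfg: GeneratorConfig) -> np.ndarray:
    """Region -> preferred-measure index; contiguous blocks cycling the four
    measures, overridden by planted signal regions."""
    n = cfg.n_regions
    if cfg.preferred_measure is not None:
        pref = np.full(n, MEASURES.index(cfg.preferred_measure))
    else:
        block = int(np.ceil(n / len(MEASURES)))
        pref = np.repeat(np.arange(len(MEASURES)), block)[:n]
    for spec in cfg.signal_regions:
        pref[spec.region] = MEASURES.index(spec.measure)
    return pref


def _latent_groups(signal: Sequence[SignalSpec]) -> list[str | None]:
    groups: list[str | None] = []
    for spec in signal:
        if spec.condition not in groups:
            groups.append(spec.condition)
    return groups


def generate_phenotype(
    cfg: GeneratorConfig,
    latents: dict[str | None, np.ndarray],
    rng: np.random.Generator,
) -> tuple[ParticipantTable, dict]:
    """Phenotype + covariates given the per-group signal latents.

    g is a weighted sum of the latent coupling deviations plus weakly
    confounded covariate components and a normal residual, reported on the
    (0.25, 0.83) scale.
    """
    n = cfg.n_participants
    conf = cfg.confound_strengths
    z_age = rng.standard_normal(n)
    z_gender = rng.standard_normal(n)
    z_hand = rng.standard_normal(n)
    z_mot = rng.standard_normal(n)
    groups = list(latents)
    share = cfg.total_signal_r2 / len(groups) if groups else 0.0
    alpha = np.sqrt(share)
    conf_var = sum(v**2 for v in conf.values())
    resid_var = 1.0 - cfg.total_signal_r2 * bool(groups) - conf_var
    if resid_var <= 0:
        raise ValidationError("signal + confound variance exceeds unit variance")
    core = (
        sum(alpha * latents[gr] for gr in groups)
        + conf["age"] * z_age + conf["gender"] * z_gender
        + conf["handedness"] * z_hand + conf["motion"] * z_mot
        + np.sqrt(resid_var) * rng.standard_normal(n)
    )
    df = pd.DataFrame({
        "participant_id": [f"sub-{p + 1:04d}" for p in range(n)],
        "g": G_MEAN + G_SD * core,
        "age": np.round(29.0 + 3.0 * z_age, 1),
        "gender": (z_gender > 0).astype(int),
        "handedness": np.clip(65.0 + 35.0 * z_hand, -100.0, 100.0),
    })
    base_motion = np.clip(0.12 + 0.03 * (-z_mot), 0.02, None)
    for cond in cfg.conditions:
        df[f"motion_{cond}"] = np.clip(
            base_motion + rng.normal(0.0, 0.01, size=n), 0.01, None
        )
    truth = {"latents": latents, "alpha": alpha, "core": core}
    return ParticipantTable(df), truth


def generate_fc(
    cfg: GeneratorConfig,
    predictors: dict[str, list],
    latents: dict[str | None, np.ndarray],
    rng: np.random.Generator,
) -> dict[tuple[str, str], FunctionalConnectome]:
    """Condition-specific FC as noisy mixtures of preferred predictor columns."""
    n = cfg.n_regions
    pref = _preferred_measures(cfg)
    lo, hi = cfg.coupling_scale
    gradient = np.linspace(hi, lo, n)  # high-coupling "unimodal" regions first
    rest_pattern = cfg.rest_divergence * rng.standard_normal(n)
    task_patterns = {
        c: cfg.task_jitter_sd * rng.standard_normal(n)
        for c in cfg.task_conditions
    }
    part_dev = cfg.participant_sd * rng.standard_normal(cfg.n_participants)
    # planted phenotype link: amplitude modulation of signal regions
    gamma = {spec: 0.5 * abs(spec.effect_r) for spec in cfg.signal_regions}
    pids = sorted(predictors)
    fcs: dict[tuple[str, str], FunctionalConnectome] = {}
    for pi, pid in enumerate(pids):
        preds = predictors[pid]
        zcols = np.empty((n, n))
        z_by_measure = [_standardize_offdiag(p.values) for p in preds]
        for i in range(n):
            zcols[:, i] = z_by_measure[pref[i]][:, i]
        for cond in cfg.conditions:
            a = gradient + cfg.condition_offsets.get(cond, 0.0) + part_dev[pi]
            if cond == cfg.conditions[0]:
                a = a + rest_pattern
            else:
                a = a + task_patterns[cond]
            for spec in cfg.signal_regions:
                if spec.condition is not None and spec.condition != cond:
                    continue
                if cond == cfg.conditions[0]:
                    continue  # phenotype link planted in task coupling only
                u = latents[spec.condition][pi]
                a[spec.region] += np.sign(spec.effect_r) * gamma[spec] * u
            cols = a[None, :] * zcols + cfg.noise_sd * rng.standard_normal((n, n))
            values = 0.3 * (cols + cols.T) / 2.0
            np.fill_diagonal(values, 0.0)
            fcs[(pid, cond)] = FunctionalConnectome(pid, cond, values)
    return fcs


def generate_cohort(
    cfg: GeneratorConfig | None = None,
    analysis_cfg: AnalysisConfig | None = None,
) -> tuple[Cohort, dict[str, list], dict]:
    """Full matrix-level cohort: SCs, predictor matrices, FCs, phenotypes.

    Returns (cohort, predictors, ground_truth); ground truth carries the
    latent signal factors, the preferred-measure map and the generator config.
    """
    cfg = cfg or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    scs = generate_sc(cfg, rng)
    acfg = analysis_cfg or AnalysisConfig()
    predictors = {sc.participant_id: all_predictors(sc, acfg) for sc in scs}
    groups = _latent_groups(cfg.signal_regions)
    latents = {gr: rng.standard_normal(cfg.n_participants) for gr in groups}
    fcs = generate_fc(cfg, predictors, latents, rng)
    participants, truth = generate_phenotype(cfg, latents, rng)
    truth.update({
        "preferred_measures": _preferred_measures(cfg),
        "config": cfg,
    })
    cohort = Cohort({sc.participant_id: sc for sc in scs}, fcs, participants,
                    list(cfg.conditions))
    return cohort, predictors, truth


# ---------------------------------------------------------------------------
# coupling-level generator


@dataclass
class CouplingGenConfig:
    """Study conditions for the coupling-level generator.

    Effect sizes are exact here: each planted :class:`SignalSpec` produces
    corr(phenotype, r_C[region, measure]) = effect_r by construction, and the
    across-participant SD of brain-average coupling equals roughly
    sqrt(participant_sd^2 + interaction_sd^2) (~0.02 at the defaults).
    """

    n_participants: int = 500
    n_regions: int = 60
    conditions: tuple[str, ...] = HCP_CONDITIONS
    measures: tuple[str, ...] = MEASURES
    base_gradient: tuple[float, float] = (0.25, 0.55)
    measure_offsets: dict[str, float] = field(
        default_factory=lambda: {"CoS": 0.05, "SI": -0.05}
    )
    condition_offsets: dict[str, float] = field(
        default_factory=lambda: {"RES": 0.05, "EMO": -0.05}
    )
    participant_sd: float = 0.015
    interaction_sd: float = 0.012
    region_noise_sd: float = 0.05
    signal: tuple[SignalSpec, ...] = ()
    total_signal_r2: float = 0.10
    confound_strengths: dict[str, float] = field(default_factory=_default_confounds)
    motion_on_coupling: float = 0.0

    def replace(self, **kw) -> "CouplingGenConfig":
        return replace(self, **kw)


def generate_coupling_cohort(
    cfg: CouplingGenConfig | None = None, seed: int = 0
) -> tuple[CouplingTable, ParticipantTable, dict]:
    """Coupling table + participant table with exactly planted structure.

    Signal entries with ``condition=None`` apply to (and share one latent
    across) all task conditions; entries naming a condition get a latent per
    condition group.  The planted total phenotype signal variance is
    ``total_signal_r2``, split evenly over latent groups; per-entry
    ``effect_r`` must stay below sqrt(share) for the required loading to
    exist.
    """
    cfg = cfg or CouplingGenConfig()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 77]))
    n, R = cfg.n_participants, cfg.n_regions
    conds, meas = list(cfg.conditions), list(cfg.measures)
    nC, nM = len(conds), len(meas)

    lo, hi = cfg.base_gradient
    base = (
        np.linspace(hi, lo, R)[None, None, :]
        + np.array([cfg.measure_offsets.get(m, 0.0) for m in meas])[None, :, None]
        + np.array([cfg.condition_offsets.get(c, 0.0) for c in conds])[:, None, None]
    )  # (cond, meas, region)

    groups = _latent_groups(cfg.signal)
    latents = {gr: rng.standard_normal(n) for gr in groups}
    share = cfg.total_signal_r2 / len(groups) if groups else 0.0
    alpha = np.sqrt(share)
    sigma_tot = np.sqrt(
        cfg.participant_sd**2 + cfg.interaction_sd**2 + cfg.region_noise_sd**2
    )

    values = np.broadcast_to(base, (n, nC, nM, R)).copy()
    values += cfg.participant_sd * rng.standard_normal(n)[:, None, None, None]
    values += cfg.interaction_sd * rng.standard_normal((n, nC))[:, :, None, None]
    values += cfg.region_noise_sd * rng.standard_normal((n, nC, nM, R))

    task_conds = [c for c in conds if c != conds[0]]
    for spec in cfg.signal:
        if abs(spec.effect_r) >= alpha:
            raise ValidationError(
                f"effect_r {spec.effect_r} unreachable: latent group explains "
                f"only {share:.3f} of phenotype variance (max |r| {alpha:.3f})"
            )
        lam = abs(spec.effect_r) * sigma_tot / np.sqrt(
            alpha**2 - spec.effect_r**2
        )
        u = latents[spec.condition]
        mi = meas.index(spec.measure)
        targets = [spec.condition] if spec.condition else task_conds
        for cond in targets:
            ci = conds.index(cond)
            values[:, ci, mi, spec.region] += np.sign(spec.effect_r) * lam * u

    # phenotype + covariates
    conf = cfg.confound_strengths
    z_age = rng.standard_normal(n)
    z_gender = rng.standard_normal(n)
    z_hand = rng.standard_normal(n)
    z_mot = rng.standard_normal(n)
    conf_var = sum(v**2 for v in conf.values())
    resid_var = 1.0 - cfg.total_signal_r2 * bool(groups) - conf_var
    if resid_var <= 0:
        raise ValidationError("signal + confound variance exceeds unit variance")
    core = (
        sum(alpha * latents[gr] for gr in groups)
        + conf["age"] * z_age + conf["gender"] * z_gender
        + conf["handedness"] * z_hand + conf["motion"] * z_mot
        + np.sqrt(resid_var) * rng.standard_normal(n)
    )
    if cfg.motion_on_coupling:
        values += cfg.motion_on_coupling * z_mot[:, None, None, None]
    np.clip(values, -0.999, 0.999, out=values)

    pids = [f"sub-{p + 1:04d}" for p in range(n)]
    df = pd.DataFrame({
        "participant_id": pids,
        "g": G_MEAN + G_SD * core,
        "age": np.round(29.0 + 3.0 * z_age, 1),
        "gender": (z_gender > 0).astype(int),
        "handedness": np.clip(65.0 + 35.0 * z_hand, -100.0, 100.0),
    })
    base_motion = np.clip(0.12 + 0.03 * (-z_mot), 0.02, None)
    for cond in conds:
        df[f"motion_{cond}"] = np.clip(
            base_motion + rng.normal(0.0, 0.01, size=n), 0.01, None
        )
    table = CouplingTable(values, pids, conds, meas)
    truth = {
        "latents": latents,
        "alpha": alpha,
        "core": core,
        "signal": list(cfg.signal),
        "config": cfg,
    }
    return table, ParticipantTable(df), truth


# ---------------------------------------------------------------------------
# time-series mode


def timeseries_for_fc(
    fc: FunctionalConnectome, n_frames: int, rng: np.random.Generator
) -> np.ndarray:
    """BOLD-like time series whose correlation structure matches a target FC.

    The Fisher-z FC is mapped back to correlations, repaired to the nearest
    positive-definite correlation matrix, and sampled as multivariate normal
    frames; feeding the result through ``fc_from_timeseries`` recovers the
    target up to sampling error.
    """
    r = np.tanh(fc.values)
    np.fill_diagonal(r, 1.0)
    vals, vecs = np.linalg.eigh(r)
    vals = np.clip(vals, 1e-6, None)
    cov = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(cov))
    corr = cov / np.outer(d, d)
    chol = np.linalg.cholesky(corr + 1e-10 * np.eye(len(d)))
    return rng.standard_normal((n_frames, len(d))) @ chol.T
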