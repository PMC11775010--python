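"""Seeded synthetic-data generator for the whole pipeline.

The generator emulates the statistical structure the analysis assumes, so
every stage can be exercised end to end without sequencing data:

* a cohort whose marginals mirror the study population (13 CHD / 30 HC,
  delivery split, feeding, maternal covariates, SpO2 ~ N(90.9, 3.4) for
  patients, truncated to (70, 100]);
* genus compositions from a logistic-normal model — ilr coordinates are
  group baseline + SpO2 effect + delivery effect + Gaussian noise — which
  is exactly the family under which the downstream ilr linear regression
  is correctly specified, making parameter recovery a meaningful check;
* counts by multinomial sampling at a configurable depth, with optional
  zero-inflation (post-multinomial thinning) so zero imputation has real
  work to do;
* optional planted cluster structure (per-sample baseline drawn from one
  of several ilr centers) with the true labels returned for recovery
  checks;
* perfusion records whose regional SO2 is linear in SpO2 with small noise,
  reproducing the tight SpO2/tissue-oxygenation correlation the physiology
  module quantifies.

All randomness flows from ``GeneratorConfig.seed`` through one
``numpy.random.Generator``; identical configs give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .composition import ilr_inverse, make_ilr_basis
from .io_tables import AbundanceTable, PerfusionRecord, SampleMetadata
from . import study_tables as study

__all__ = ["GeneratorConfig", "simulate_cohort", "simulate_abundances",
           "simulate_perfusion"]


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic cohort; defaults are the study conditions."""

    seed: int = 0
    n_chd: int = study.N_CHD
    n_hc: int = study.N_HC
    genera: Sequence[str] = field(default_factory=lambda: list(study.CORE_GENERA))

    # cohort marginals (probabilities from the published counts)
    p_cesarean: dict = field(default_factory=lambda: {"CHD": 6 / 13, "HC": 17 / 30})
    p_feeding: dict = field(default_factory=lambda: {
        "CHD": {"breastfeeding": 8 / 13, "formula": 3 / 13, "mixed": 2 / 13},
        "HC": {"breastfeeding": 20 / 30, "formula": 10 / 30, "mixed": 0.0}})
    p_maternal_nutrition: dict = field(default_factory=lambda: {
        "CHD": {"meat": 1.0}, "HC": {"meat": 26 / 30, "vegetarian": 2 / 30,
                                     "unknown": 2 / 30}})
    p_antibiotics: dict = field(default_factory=lambda: {"CHD": 4 / 13, "HC": 21 / 30})
    p_gbs: dict = field(default_factory=lambda: {"CHD": 1 / 13, "HC": 3 / 30})
    spo2_mean: float = study.SPO2_MEAN
    spo2_sd: float = study.SPO2_SD
    spo2_bounds: tuple = (70.0, 100.0)
    birth_weight: dict = field(default_factory=lambda: {
        "CHD": (3153.0, 539.0), "HC": (3332.0, 519.0)})
    gestational_age: dict = field(default_factory=lambda: {
        "CHD": (38.2, 2.7), "HC": (39.0, 1.7)})
    age_days: dict = field(default_factory=lambda: {
        "CHD": (7.8, 3.1), "HC": (1.7, 1.5)})
    replicate_counts: Sequence[int] = (2, 3)   # per CHD subject, drawn uniformly
    replicate_probs: Optional[Sequence[float]] = None

    # composition model (ilr scale)
    baseline_ilr: dict = field(default_factory=dict)   # group -> (D-1,) vector
    spo2_effect: Optional[np.ndarray] = None           # per ilr coord per % (CHD)
    delivery_effect: Optional[np.ndarray] = None       # cesarean minus vaginal
    noise_sd: float = 0.5                              # isotropic sigma
    spo2_center: float = 90.0                          # SpO2 centering for effects
    depth: int = 50_000                                # multinomial reads/sample
    zero_inflation: float = 0.05                       # dropout prob. per rare cell
    zero_inflation_threshold: float = 0.01             # "rare" = rel. abundance below

    # planted clusters (optional)
    cluster_centers: Optional[np.ndarray] = None       # (n_clusters, D-1)
    cluster_proportions: Optional[Sequence[float]] = None

    # perfusion model
    so2_slope: float = 1.15
    so2_intercept: dict = field(default_factory=lambda: {"rl": -46.0, "ru": -45.5})
    so2_noise_sd: float = 0.4
    pv_velocity_range: tuple = (8.0, 16.0)        # cm/s
    pv_diameter_range: tuple = (0.3, 0.5)         # cm
    o2c_flow_mean: dict = field(default_factory=lambda: {"rl": 268.8, "ru": 286.3})
    o2c_flow_sd: float = 57.6
    o2c_velocity_mean: dict = field(default_factory=lambda: {"rl": 69.7, "ru": 71.8})
    o2c_velocity_sd: float = 9.0
    sma_psv: tuple = (108.5, 55.0)
    sma_edv: tuple = (16.3, 10.4)

    def __post_init__(self) -> None:
        self.genera = list(self.genera)
        if self.depth <= 0:
            raise ValueError("sequencing depth must be > 0")
        if not 0 <= self.zero_inflation < 1:
            raise ValueError("zero_inflation must be in [0, 1)")
        if self.noise_sd < 0 or self.so2_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.cluster_proportions is not None:
            props = np.asarray(self.cluster_proportions, float)
            if not np.isclose(props.sum(), 1.0):
                raise ValueError("cluster proportions must sum to 1")

    @property
    def n_parts(self) -> int:
        return len(self.genera)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _default_baseline(config: GeneratorConfig, group: str) -> np.ndarray:
    """Mild group-specific baseline: patients lean toward the first genera
    (Enterococcus/Staphylococcus-dominated), controls are more even."""
    D = config.n_parts
    if group in config.baseline_ilr:
        return np.asarray(config.baseline_ilr[group], float)
    basis = make_ilr_basis(config.genera)
    decay = 0.35 if group == "CHD" else 0.2
    logp = -decay * np.arange(D)
    p = np.exp(logp) / np.exp(logp).sum()
    return np.log(p) @ basis.contrasts.T


def _truncated_normal(rng, mean, sd, lo, hi, size):
    out = np.empty(size)
    for i in range(size):
        x = rng.normal(mean, sd)
        while not (lo < x <= hi):
            x = rng.normal(mean, sd)
        out[i] = x
    return out


def _categorical(rng, probs: dict) -> str:
    names = list(probs)
    p = np.array([probs[k] for k in names], float)
    rest = 1.0 - p.sum()
    if rest > 1e-9:
        names.append("__rest__")
        p = np.append(p, rest)
    return str(rng.choice(names, p=p / p.sum()))


def simulate_cohort(config: GeneratorConfig) -> list[SampleMetadata]:
    """Draw subject-level metadata; CHD subjects contribute replicate
    samples (successive visit indices), controls one sample each."""
    rng = config.rng()
    meta: list[SampleMetadata] = []
    spo2_chd = _truncated_normal(rng, config.spo2_mean, config.spo2_sd,
                                 *config.spo2_bounds, config.n_chd)
    for group, n in (("CHD", config.n_chd), ("HC", config.n_hc)):
        # delivery split is an exact cohort marginal, not a per-subject draw
        n_ces = int(round(config.p_cesarean[group] * n))
        deliveries = np.array(["cesarean"] * n_ces + ["vaginal"] * (n - n_ces))
        rng.shuffle(deliveries)
        for i in range(n):
            subject = f"{'P' if group == 'CHD' else 'C'}{i + 1:02d}"
            delivery = str(deliveries[i])
            feeding = _categorical(rng, config.p_feeding[group])
            feeding = None if feeding == "__rest__" else feeding
            nutrition = _categorical(rng, config.p_maternal_nutrition[group])
            nutrition = "unknown" if nutrition == "__rest__" else nutrition
            bw = rng.normal(*config.birth_weight[group])
            ga = rng.normal(*config.gestational_age[group])
            age = max(1.0, rng.normal(*config.age_days[group]))
            common = dict(
                subject_id=subject, group=group, delivery=delivery,
                spo2=float(spo2_chd[i]) if group == "CHD" else None,
                age_days=round(age, 1), birth_weight_g=round(bw),
                gestational_age_wk=round(ga, 1), feeding=feeding,
                maternal_nutrition=nutrition,
                maternal_antibiotics=bool(rng.random() < config.p_antibiotics[group]),
                gbs_colonization=bool(rng.random() < config.p_gbs[group]),
            )
            if group == "CHD":
                reps = config.replicate_counts
                n_rep = int(rng.choice(reps, p=config.replicate_probs))
            else:
                n_rep = 1
            for v in range(1, n_rep + 1):
                meta.append(SampleMetadata(sample_id=f"{subject}_v{v}",
                                           visit=v, **common))
    return meta


def simulate_abundances(config: GeneratorConfig,
                        metadata: Sequence[SampleMetadata],
                        return_cluster_labels: bool = False):
    """Logistic-normal-multinomial genus counts for each metadata sample.

    ilr mean = baseline (group- or planted-cluster-specific)
               + (SpO2 - center) * spo2_effect    [patients with SpO2]
               + delivery_effect                  [cesarean]
    Counts are multinomial at ``config.depth``; with zero inflation, each
    nonzero cell below the rare-cell threshold is zeroed with the
    configured probability.
    Returns the taxa x samples table (and the planted labels if asked).
    """
    rng = np.random.default_rng(config.seed + 1)
    basis = make_ilr_basis(config.genera)
    D = config.n_parts
    p = D - 1
    spo2_eff = (np.zeros(p) if config.spo2_effect is None
                else np.asarray(config.spo2_effect, float))
    dlv_eff = (np.zeros(p) if config.delivery_effect is None
               else np.asarray(config.delivery_effect, float))
    planted = config.cluster_centers is not None
    labels: dict[str, int] = {}
    cluster_of_subject: dict[str, int] = {}
    if planted:
        # exact apportionment (largest remainders), shuffled: planted group
        # sizes are part of the design, not a random draw
        subjects = list(dict.fromkeys(m.subject_id for m in metadata))
        k = len(config.cluster_centers)
        props = (np.asarray(config.cluster_proportions, float)
                 if config.cluster_proportions is not None
                 else np.full(k, 1.0 / k))
        quota = props * len(subjects)
        sizes = np.floor(quota).astype(int)
        for c in np.argsort(-(quota - sizes))[:len(subjects) - sizes.sum()]:
            sizes[c] += 1
        pool = np.repeat(np.arange(k), sizes)
        rng.shuffle(pool)
        cluster_of_subject = dict(zip(subjects, (int(c) for c in pool)))
    counts = np.zeros((D, len(metadata)))
    for j, m in enumerate(metadata):
        if planted:
            c = cluster_of_subject[m.subject_id]
            labels[m.sample_id] = c
            mu = np.asarray(config.cluster_centers[c], float).copy()
        else:
            mu = _default_baseline(config, m.group).copy()
        if m.spo2 is not None:
            mu = mu + (m.spo2 - config.spo2_center) * spo2_eff
        if m.delivery == "cesarean":
            mu = mu + dlv_eff
        coords = mu + rng.normal(0.0, config.noise_sd, size=p)
        comp = ilr_inverse(coords[None, :], basis).values[0]
        counts[:, j] = rng.multinomial(config.depth, comp)
    if config.zero_inflation > 0:
        # sequencing dropout hits rare taxa: thin low-abundance cells to zero
        low = (counts > 0) & (counts < config.zero_inflation_threshold * config.depth)
        drop = low & (rng.random(counts.shape) < config.zero_inflation)
        counts[drop] = 0.0
    table = AbundanceTable(list(config.genera), [m.sample_id for m in metadata],
                           counts)
    if return_cluster_labels:
        return table, labels
    return table


def simulate_perfusion(config: GeneratorConfig,
                       metadata: Sequence[SampleMetadata]) -> list[PerfusionRecord]:
    """One perfusion record per CHD subject, with regional SO2 linear in
    the subject's SpO2 plus small Gaussian noise."""
    rng = np.random.default_rng(config.seed + 2)
    seen: set[str] = set()
    records: list[PerfusionRecord] = []
    for m in metadata:
        if m.group != "CHD" or m.subject_id in seen:
            continue
        seen.add(m.subject_id)
        if m.spo2 is None:
            raise ValueError(f"CHD subject {m.subject_id} has no SpO2")
        rl = config.so2_intercept["rl"] + config.so2_slope * m.spo2 \
            + rng.normal(0, config.so2_noise_sd)
        ru = config.so2_intercept["ru"] + config.so2_slope * m.spo2 \
            + rng.normal(0, config.so2_noise_sd)
        weight = (m.birth_weight_g / 1000.0 if m.birth_weight_g is not None
                  else rng.uniform(2.5, 4.0))
        records.append(PerfusionRecord(
            subject_id=m.subject_id,
            spo2=m.spo2,
            rl_so2=float(np.clip(rl, 1.0, 100.0)),
            ru_so2=float(np.clip(ru, 1.0, 100.0)),
            rl_flow=float(rng.normal(config.o2c_flow_mean["rl"], config.o2c_flow_sd)),
            ru_flow=float(rng.normal(config.o2c_flow_mean["ru"], config.o2c_flow_sd)),
            rl_velocity=float(rng.normal(config.o2c_velocity_mean["rl"],
                                         config.o2c_velocity_sd)),
            ru_velocity=float(rng.normal(config.o2c_velocity_mean["ru"],
                                         config.o2c_velocity_sd)),
            sma_psv=float(max(5.0, rng.normal(*config.sma_psv))),
            sma_edv=float(max(0.0, rng.normal(*config.sma_edv))),
            pv_mean_velocity=float(rng.uniform(*config.pv_velocity_range)),
            pv_diameter_cm=float(rng.uniform(*config.pv_diameter_range)),
            body_weight_kg=float(weight),
        ))
    return records
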