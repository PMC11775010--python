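"""Statistical validation experiments for the compositional model.

These are the package's own checks that the inferential machinery behaves
as claimed, run on synthetic cohorts whose generative family (logistic
normal in ilr coordinates, multinomially sampled to counts) is the one
under which the ilr linear model is correctly specified:

* null calibration — with no oxygenation or delivery effect, the MANOVA
  p-value for the SpO2 term must be Uniform(0, 1), so the type-I rate at
  any alpha is the nominal one;
* permutation cross-check — the analytic Wilks-F p-value must agree with
  a model-free permutation p-value of the same statistic on the same data;
* parameter recovery — with a known SpO2 effect planted, the fitted slopes
  must cover the truth at the advertised standard-error scale;
* planted-cluster recovery — Aitchison-geometry clustering must perfectly
  recover well-separated planted clusters (adjusted Rand index 1).

Sequencing dropout (zero inflation) is off here: these experiments probe
the statistical procedure under its own model assumptions; the pipeline
tests exercise the dropout-plus-imputation path separately.
"""

from __future__ import annotations

import numpy as np

from . import coda_model, composition, io_tables
from .clustering import cut_clusters, hierarchical_cluster
from .synthetic_data import (GeneratorConfig, simulate_abundances,
                             simulate_cohort)
from .study_tables import CORE_GENERA

__all__ = ["model_dataset", "null_manova_pvalues", "manova_permutation_pvalue",
           "slope_recovery", "planted_cluster_recovery", "adjusted_rand_index"]


def model_dataset(seed: int, n_chd: int = 13, n_genera: int = 10,
                  k_core: int = 9, spo2_effect=None, delivery_effect=None,
                  noise_sd: float = 0.5, zero_inflation: float = 0.0,
                  replicate_counts=(1,)):
    """Simulate a patient cohort and run it up to the fitted ilr model.

    Returns (fit, basis, core composition, config).  ``spo2_effect`` may be
    a scalar (applied to every ilr coordinate) or a length k_core-1 vector.
    """
    p = k_core - 1
    if spo2_effect is not None and np.ndim(spo2_effect) == 0:
        spo2_effect = np.full(p, float(spo2_effect))
    if delivery_effect is not None and np.ndim(delivery_effect) == 0:
        delivery_effect = np.full(p, float(delivery_effect))
    config = GeneratorConfig(
        seed=seed, n_chd=n_chd, n_hc=0, genera=CORE_GENERA[:n_genera],
        noise_sd=noise_sd, zero_inflation=zero_inflation,
        replicate_counts=replicate_counts,
        spo2_effect=_pad(spo2_effect, n_genera - 1),
        delivery_effect=_pad(delivery_effect, n_genera - 1),
    )
    meta = simulate_cohort(config)
    table = simulate_abundances(config, meta)
    first = io_tables.select_first_visit(table, meta)
    by_id = {m.sample_id: m for m in meta}
    comp = composition.from_abundance(first)
    core = composition.select_core(comp, k_core)
    core = composition.impute_zeros(core)
    basis = composition.make_ilr_basis(core.parts)
    coords = composition.ilr(core, basis)
    spo2 = [by_id[s].spo2 for s in core.samples]
    delivery = [by_id[s].delivery for s in core.samples]
    spec = coda_model.build_model(coords, spo2, delivery, interaction=True)
    return coda_model.fit_multivariate_lm(spec), basis, core, config


def _pad(effect, width):
    """Embed a core-scale effect vector into the full-genus ilr space."""
    if effect is None:
        return None
    eff = np.zeros(width)
    eff[:len(effect)] = effect
    return eff


def null_manova_pvalues(n_sims: int = 500, seed: int = 0, n_chd: int = 13,
                        n_genera: int = 10, k_core: int = 9) -> np.ndarray:
    """SpO2-term MANOVA p-values over seeded null cohorts (no effects)."""
    out = np.empty(n_sims)
    for i in range(n_sims):
        fit, *_ = model_dataset(seed + i, n_chd=n_chd, n_genera=n_genera,
                                k_core=k_core)
        out[i] = coda_model.manova(fit, "spo2").p_value
    return out


def manova_permutation_pvalue(fit: coda_model.MultivariateLMFit,
                              n_perm: int = 2000, seed: int = 0) -> float:
    """Permutation p-value for the SpO2 term of a fitted model.

    SpO2 values are permuted across samples (the design, including the
    interaction column, is rebuilt each time) and the sequential Wilks
    lambda recomputed; smaller lambda is more extreme.  Uses the add-one
    permutation estimator.
    """
    rng = np.random.default_rng(seed)
    spec = fit.spec
    obs = coda_model.manova(fit, "spo2").statistic
    spo2 = np.asarray(spec.spo2, float)
    delivery = spec.design[:, spec.term_map["delivery"][0]]
    interaction = "spo2:delivery" in spec.term_map
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(spo2)
        pspec = coda_model.build_model(spec.response, perm, delivery,
                                       interaction=interaction)
        pfit = coda_model.fit_multivariate_lm(pspec)
        if coda_model.manova(pfit, "spo2").statistic <= obs:
            hits += 1
    return (hits + 1) / (n_perm + 1)


def slope_recovery(n_reps: int = 100, seed: int = 0, n: int = 200,
                   k_core: int = 9, effect: float = 0.05,
                   se_factor: float = 3.0) -> float:
    """Fraction of replicates whose fitted SpO2 slopes all lie within
    ``se_factor`` standard errors of the planted truth.

    The truth is a uniform per-% effect on every ilr coordinate of the
    k_core-genus composition; SEs come from the usual OLS formula
    sqrt([(X'X)^-1]_jj * E_kk / df_e) per coordinate.
    """
    hits = 0
    for i in range(n_reps):
        fit, *_ = model_dataset(seed + i, n_chd=n, n_genera=k_core,
                                k_core=k_core, spo2_effect=effect)
        spec = fit.spec
        j = spec.term_map["spo2"][0]
        xtx_inv = np.linalg.inv(spec.design.T @ spec.design)
        sigma2 = np.diag(fit.residual_sscp) / fit.error_df
        se = np.sqrt(xtx_inv[j, j] * sigma2)
        if np.all(np.abs(fit.coef[j] - effect) <= se_factor * se):
            hits += 1
    return hits / n_reps


def adjusted_rand_index(a, b) -> float:
    """Chance-corrected agreement between two partitions."""
    from sklearn.metrics import adjusted_rand_score
    return float(adjusted_rand_score(list(a), list(b)))


def planted_cluster_recovery(n_seeds: int = 20, seed: int = 0,
                             n_subjects: int = 13, n_clusters: int = 3,
                             separation: float = 4.0, spread: float = 0.1,
                             linkage: str = "complete") -> list[float]:
    """Adjusted Rand index of dendrogram cuts against planted labels.

    Centers sit on distinct ilr coordinate axes at the given separation;
    with the default separation/spread the between-center Aitchison
    distance exceeds ten times the within-cluster spread, so recovery
    should be exact (ARI 1) for any sensible linkage.
    """
    genera = CORE_GENERA[:9]
    p = len(genera) - 1
    centers = np.zeros((n_clusters, p))
    for c in range(n_clusters):
        centers[c, c % p] = separation * (1 if c < p else -1)
    aris = []
    for i in range(n_seeds):
        config = GeneratorConfig(
            seed=seed + i, n_chd=n_subjects, n_hc=0, genera=genera,
            noise_sd=spread, zero_inflation=0.0, replicate_counts=(1,),
            cluster_centers=centers)
        meta = simulate_cohort(config)
        table, labels = simulate_abundances(config, meta,
                                            return_cluster_labels=True)
        comp = composition.impute_zeros(composition.from_abundance(table))
        dend = hierarchical_cluster(comp, linkage)
        found = cut_clusters(dend, n_clusters)
        truth = [labels[s] for s in comp.samples]
        pred = [found.labels[s] for s in comp.samples]
        aris.append(adjusted_rand_index(truth, pred))
    return aris
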