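"""Multivariate linear model of gut composition on oxygen saturation and
delivery mode, with MANOVA assessment and back-transformed prediction.

The model operates in ilr coordinates, where a D-part composition is an
unconstrained (D-1)-vector and ordinary least squares is valid:

    ilr(composition_i) = b0 + b1*SpO2_i + b2*delivery_i
                         + b3*SpO2_i*delivery_i + eps_i

Each term is assessed by MANOVA with sequential (Type I) sums of squares in
the order SpO2, delivery, interaction.  Wilks' lambda is used; every
hypothesis term here has a single degree of freedom, for which all four
classical MANOVA statistics coincide and the approximate F is exact with
degrees of freedom (p, error_df - p + 1) where p = D - 1.  Fitted ilr
predictions over an SpO2 grid are mapped back through the inverse ilr to
give composition-vs-oxygenation curves per delivery mode.

Statistics are invariant to the choice of orthonormal ilr basis; only the
coordinates themselves depend on it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .composition import CompositionMatrix, IlrBasis, IlrCoordinates, ilr_inverse

__all__ = [
    "ModelSpec",
    "MultivariateLMFit",
    "ManovaEntry",
    "ManovaResult",
    "PredictionCurve",
    "encode_delivery",
    "build_model",
    "fit_multivariate_lm",
    "manova",
    "predict_composition",
    "adjusted_r2",
]

logger = logging.getLogger(__name__)

DELIVERY_CODES = {"vaginal": 0.0, "cesarean": 1.0}


def encode_delivery(levels: Sequence[str]) -> np.ndarray:
    """Binary contrast for delivery mode: 0 = vaginal (reference), 1 = cesarean."""
    try:
        return np.array([DELIVERY_CODES[x] for x in levels], dtype=float)
    except KeyError as err:
        raise ValueError(f"unknown delivery level {err.args[0]!r}") from None


@dataclass
class ModelSpec:
    """Response ilr coordinates plus a design matrix and its term layout."""

    response: IlrCoordinates
    design: np.ndarray                       # n x q
    term_map: dict[str, list[int]]           # term name -> design column indices
    column_names: list[str]
    spo2: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        n, q = self.design.shape
        if self.response.coords.shape[0] != n:
            raise ValueError("design and response have different numbers of rows")
        if n <= q:
            raise ValueError(f"need more observations ({n}) than design columns ({q})")
        rank = np.linalg.matrix_rank(self.design)
        if rank < q:
            # identify columns not adding rank, in order
            bad = []
            kept: list[int] = []
            for j in range(q):
                cand = kept + [j]
                if np.linalg.matrix_rank(self.design[:, cand]) == len(kept):
                    bad.append(self.column_names[j])
                else:
                    kept.append(j)
            raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")


def build_model(response: IlrCoordinates, spo2: Sequence[float],
                delivery: Sequence[str] | np.ndarray,
                interaction: bool = True) -> ModelSpec:
    """Assemble the intercept + SpO2 + delivery (+ interaction) design."""
    spo2 = np.asarray(spo2, dtype=float)
    if np.any(~np.isfinite(spo2)):
        raise ValueError("SpO2 contains missing values")
    dlv = (np.asarray(delivery, dtype=float)
           if not isinstance(delivery[0], str) else encode_delivery(delivery))
    n = len(spo2)
    cols = [np.ones(n), spo2, dlv]
    names = ["intercept", "spo2", "delivery"]
    term_map = {"intercept": [0], "spo2": [1], "delivery": [2]}
    if interaction:
        cols.append(spo2 * dlv)
        names.append("spo2:delivery")
        term_map["spo2:delivery"] = [3]
    return ModelSpec(response, np.column_stack(cols), term_map, names, spo2=spo2)


@dataclass
class MultivariateLMFit:
    spec: ModelSpec
    coef: np.ndarray           # q x p
    residual_sscp: np.ndarray  # p x p
    error_df: int

    @property
    def fitted(self) -> np.ndarray:
        return self.spec.design @ self.coef

    @property
    def residuals(self) -> np.ndarray:
        return self.spec.response.coords - self.fitted


def _ols_sscp(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """OLS coefficients and residual SSCP for response matrix Y on X."""
    B, *_ = np.linalg.lstsq(X, Y, rcond=None)
    R = Y - X @ B
    return B, R.T @ R


def fit_multivariate_lm(spec: ModelSpec) -> MultivariateLMFit:
    """Ordinary least squares per ilr coordinate."""
    Y = spec.response.coords
    B, E = _ols_sscp(spec.design, Y)
    return MultivariateLMFit(spec, B, E, spec.design.shape[0] - spec.design.shape[1])


@dataclass
class ManovaEntry:
    term: str
    hypothesis_sscp: np.ndarray
    error_sscp: np.ndarray
    statistic_name: str
    statistic: float      # Wilks' lambda
    approx_f: float
    df_num: float
    df_den: float
    p_value: float


ManovaResult = dict  # term name -> ManovaEntry


def _wilks_f(lam: float, p: int, df_h: int, df_e: int) -> tuple[float, float, float, float]:
    """Rao's F approximation for Wilks' lambda (exact when min(p, df_h) <= 2)."""
    pq = p * df_h
    denom = p ** 2 + df_h ** 2 - 5
    t = np.sqrt((p ** 2 * df_h ** 2 - 4) / denom) if denom > 0 else 1.0
    w = df_e + df_h - (p + df_h + 1) / 2.0
    df1 = float(pq)
    df2 = w * t - (pq - 2) / 2.0
    if df2 <= 0:
        raise ValueError(
            f"insufficient error df for {p} responses (denominator df {df2:g} <= 0)"
        )
    lam_t = lam ** (1.0 / t)
    f = (1.0 - lam_t) / lam_t * df2 / df1
    pval = float(stats.f.sf(f, df1, df2))
    return float(f), df1, float(df2), pval


def manova(fit: MultivariateLMFit, term: str | None = None) -> ManovaResult | ManovaEntry:
    """Sequential (Type I) MANOVA over the model's non-intercept terms.

    The hypothesis SSCP of each term is the drop in residual SSCP when the
    term's columns are appended to all preceding columns; the error SSCP is
    the full model's residual SSCP.  Returns all entries keyed by term, or
    a single entry if ``term`` is given.
    """
    spec = fit.spec
    Y = spec.response.coords
    p = Y.shape[1]
    E = fit.residual_sscp
    df_e = fit.error_df
    if df_e - p + 1 <= 0:
        raise ValueError(
            f"insufficient error df for {p} responses "
            f"(error df {df_e}, need > {p - 1})"
        )
    entries: dict[str, ManovaEntry] = {}
    cols: list[int] = list(spec.term_map.get("intercept", []))
    _, prev_sscp = _ols_sscp(spec.design[:, cols], Y) if cols else (None, Y.T @ Y)
    for name, idx in spec.term_map.items():
        if name == "intercept":
            continue
        cols = cols + list(idx)
        _, cur_sscp = _ols_sscp(spec.design[:, cols], Y)
        H = prev_sscp - cur_sscp
        prev_sscp = cur_sscp
        lam = float(np.linalg.det(E) / np.linalg.det(H + E))
        f, df1, df2, pval = _wilks_f(lam, p, len(idx), df_e)
        entries[name] = ManovaEntry(name, H, E, "Wilks' lambda", lam, f, df1, df2, pval)
    if term is not None:
        if term not in entries:
            raise KeyError(f"term {term!r} not in model (have {list(entries)})")
        return entries[term]
    return entries


@dataclass
class PredictionCurve:
    """Predicted compositions over an SpO2 grid for one delivery level."""

    spo2_grid: np.ndarray
    delivery_level: str
    composition: CompositionMatrix

    def to_long_frame(self):
        import pandas as pd
        rows = []
        for g, row in zip(self.spo2_grid, self.composition.values):
            for part, frac in zip(self.composition.parts, row):
                rows.append({"spo2": g, "delivery": self.delivery_level,
                             "part": part, "fraction": frac})
        return pd.DataFrame(rows)


def predict_composition(fit: MultivariateLMFit, spo2_grid: Sequence[float],
                        delivery_level: str, basis: IlrBasis,
                        extrapolation_guard: float = 2.0) -> PredictionCurve:
    """Predict the composition over an SpO2 grid for one delivery level.

    Grid points outside the observed SpO2 range +/- ``extrapolation_guard``
    (percentage points) are allowed but logged as extrapolation.
    """
    grid = np.asarray(spo2_grid, dtype=float)
    if delivery_level not in DELIVERY_CODES:
        raise ValueError(f"unknown delivery level {delivery_level!r}")
    if fit.spec.spo2 is not None:
        lo = fit.spec.spo2.min() - extrapolation_guard
        hi = fit.spec.spo2.max() + extrapolation_guard
        outside = grid[(grid < lo) | (grid > hi)]
        if outside.size:
            logger.warning(
                "predicting outside observed SpO2 range [%.1f, %.1f] +/- %.1f at %s",
                fit.spec.spo2.min(), fit.spec.spo2.max(), extrapolation_guard,
                np.array2string(outside, precision=1))
    code = DELIVERY_CODES[delivery_level]
    n = grid.size
    cols = {"intercept": np.ones(n), "spo2": grid,
            "delivery": np.full(n, code), "spo2:delivery": grid * code}
    X = np.column_stack([cols[name] for name in fit.spec.column_names])
    coords = X @ fit.coef
    comp = ilr_inverse(coords, basis,
                       samples=[f"spo2_{g:g}" for g in grid])
    return PredictionCurve(grid, delivery_level, comp)


def adjusted_r2(x: Sequence[float], y: Sequence[float]) -> float:
    """Adjusted R^2 of the simple linear regression y ~ x:
    1 - (1 - R^2)(n - 1)/(n - 2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need n >= 3 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("x has zero variance")
    r = stats.linregress(x, y).rvalue
    n = x.size
    return 1.0 - (1.0 - r ** 2) * (n - 1) / (n - 2)
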