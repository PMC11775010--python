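"""Alpha-diversity indices and the median/IQR group summaries used to
describe them.

Shannon uses the natural log (nats); Simpson is the Gini–Simpson form
1 - sum(p^2), so the inverse Simpson index 1/sum(p^2) equals
1/(1 - Simpson).  Zeros are allowed (0*ln 0 := 0).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .composition import CompositionMatrix

__all__ = ["DiversityResult", "alpha_diversity", "alpha_diversity_frame",
           "group_median_iqr"]


@dataclass
class DiversityResult:
    sample_id: str
    shannon: float      # nats
    simpson: float      # in [0, 1)
    inv_simpson: float  # >= 1


def alpha_diversity(comp: CompositionMatrix) -> list[DiversityResult]:
    """Shannon, Simpson (1 - sum p^2) and inverse Simpson per sample."""
    out = []
    for sid, p in zip(comp.samples, comp.values):
        nz = p[p > 0]
        shannon = float(-(nz * np.log(nz)).sum())
        ss = float((p ** 2).sum())
        out.append(DiversityResult(sid, shannon, 1.0 - ss, 1.0 / ss))
    return out


def alpha_diversity_frame(comp: CompositionMatrix) -> pd.DataFrame:
    res = alpha_diversity(comp)
    return pd.DataFrame(
        {"shannon": [r.shannon for r in res],
         "simpson": [r.simpson for r in res],
         "inv_simpson": [r.inv_simpson for r in res]},
        index=pd.Index([r.sample_id for r in res], name="sample_id"),
    )


def group_median_iqr(values: Mapping[str, float] | pd.Series,
                     grouping: Mapping[str, str]) -> pd.DataFrame:
    """Median and interquartile range (Q3 - Q1, linear-interpolation
    quantiles) of a per-sample quantity within each group."""
    series = pd.Series(dict(values)) if not isinstance(values, pd.Series) else values
    missing = [s for s in series.index if s not in grouping]
    if missing:
        raise KeyError(f"samples without a group: {missing}")
    rows = {}
    for g in dict.fromkeys(grouping[s] for s in series.index):
        v = series[[s for s in series.index if grouping[s] == g]].to_numpy(float)
        if v.size == 0:
            raise ValueError(f"empty group {g!r}")
        q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75])  # linear interpolation
        rows[g] = {"n": v.size, "median": med, "iqr": q3 - q1}
    return pd.DataFrame.from_dict(rows, orient="index")
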