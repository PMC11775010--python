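"""Reading, writing and subject-level reshaping of the pipeline's input tables.

Three kinds of table enter the analysis: genus-level absolute abundance
tables (taxa x samples, as exported by taxonomic profilers), per-sample
clinical metadata, and bedside perfusion/oxygenation measurements.  This
module validates them on the way in, merges biological replicates into one
profile per subject, and restricts longitudinal data to the first visit.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceTable",
    "SampleMetadata",
    "PerfusionRecord",
    "read_abundance_table",
    "write_abundance_table",
    "read_metadata",
    "write_metadata",
    "read_perfusion",
    "write_perfusion",
    "merge_replicates",
    "select_first_visit",
]

GROUPS = ("CHD", "HC")
DELIVERIES = ("vaginal", "cesarean")
FEEDINGS = ("breastfeeding", "formula", "mixed", "TPN")
MATERNAL_NUTRITION = ("meat", "vegetarian", "vegan", "unknown")


@dataclass
class AbundanceTable:
    """Genus-level absolute abundances, taxa in rows, samples in columns.

    Parameters
    ----------
    taxa : list of str
        Unique genus labels, one per row of ``counts``.
    samples : list of str
        Unique sample identifiers, one per column of ``counts``.
    counts : ndarray of shape (n_taxa, n_samples)
        Nonnegative absolute abundances.
    """

    taxa: list[str]
    samples: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if len(self.taxa) < 1 or len(self.samples) < 1:
            raise ValueError("abundance table needs at least 1 taxon and 1 sample")
        if self.counts.shape != (len(self.taxa), len(self.samples)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.taxa)} taxa x {len(self.samples)} samples"
            )
        if len(set(self.taxa)) != len(self.taxa):
            dup = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise ValueError(f"duplicate taxon labels: {dup}")
        if len(set(self.samples)) != len(self.samples):
            dup = sorted({s for s in self.samples if self.samples.count(s) > 1})
            raise ValueError(f"duplicate sample ids: {dup}")
        if not np.all(np.isfinite(self.counts)):
            raise ValueError("non-finite count in abundance table")
        neg = np.argwhere(self.counts < 0)
        if neg.size:
            i, j = neg[0]
            raise ValueError(
                f"negative count at taxon {self.taxa[i]!r}, sample {self.samples[j]!r}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.taxa, columns=self.samples)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "AbundanceTable":
        return cls(
            taxa=[str(t) for t in frame.index],
            samples=[str(s) for s in frame.columns],
            counts=frame.to_numpy(dtype=float),
        )

    def select_samples(self, ids: Sequence[str]) -> "AbundanceTable":
        """Return the sub-table with the given samples, in the given order."""
        missing = [s for s in ids if s not in self.samples]
        if missing:
            raise KeyError(f"samples not in table: {missing}")
        idx = [self.samples.index(s) for s in ids]
        return AbundanceTable(list(self.taxa), [self.samples[i] for i in idx],
                              self.counts[:, idx])


@dataclass
class SampleMetadata:
    """Clinical metadata for one stool sample.

    Optional fields may be missing (``None``); any downstream step that
    needs a missing field raises instead of imputing.
    """

    sample_id: str
    subject_id: str
    group: str
    visit: int = 1
    delivery: Optional[str] = None
    spo2: Optional[float] = None
    age_days: Optional[float] = None
    birth_weight_g: Optional[float] = None
    gestational_age_wk: Optional[float] = None
    feeding: Optional[str] = None
    maternal_nutrition: Optional[str] = None
    maternal_antibiotics: Optional[bool] = None
    gbs_colonization: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.delivery is not None and self.delivery not in DELIVERIES:
            raise ValueError(f"delivery must be one of {DELIVERIES}, got {self.delivery!r}")
        if self.spo2 is not None and not (0 < self.spo2 <= 100):
            raise ValueError(f"SpO2 must be in (0, 100], got {self.spo2}")
        if self.visit < 1:
            raise ValueError("visit index must be >= 1")
        if self.feeding is not None and self.feeding not in FEEDINGS:
            raise ValueError(f"feeding must be one of {FEEDINGS}, got {self.feeding!r}")
        if (self.maternal_nutrition is not None
                and self.maternal_nutrition not in MATERNAL_NUTRITION):
            raise ValueError(f"maternal nutrition {self.maternal_nutrition!r} unknown")


@dataclass
class PerfusionRecord:
    """One neonate's oximetry, tissue-spectrometry and Doppler measurements.

    Regional values come in liver (``rl``) and periumbilical/intestinal
    (``ru``) flavours; flow and velocity from the tissue probe are in
    device arbitrary units, Doppler velocities in cm/s.
    """

    subject_id: str
    spo2: Optional[float] = None               # pulse-oximetry SpO2, %
    rl_so2: Optional[float] = None             # liver regional SO2, %
    ru_so2: Optional[float] = None             # periumbilical regional SO2, %
    rl_flow: Optional[float] = None            # AU
    ru_flow: Optional[float] = None            # AU
    rl_velocity: Optional[float] = None        # AU
    ru_velocity: Optional[float] = None        # AU
    sma_psv: Optional[float] = None            # SMA peak systolic velocity, cm/s
    sma_edv: Optional[float] = None            # SMA end-diastolic velocity, cm/s
    pv_mean_velocity: Optional[float] = None   # portal vein mean velocity, cm/s
    pv_diameter_cm: Optional[float] = None
    body_weight_kg: Optional[float] = None

    def __post_init__(self) -> None:
        if self.pv_diameter_cm is not None and self.pv_diameter_cm < 0:
            raise ValueError("portal vein diameter must be >= 0")
        if self.spo2 is not None and not (0 < self.spo2 <= 100):
            raise ValueError(f"SpO2 must be in (0, 100], got {self.spo2}")


# ---------------------------------------------------------------------------
# abundance table I/O

def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_abundance_table(path: str | Path, orientation: str = "taxa_rows") -> AbundanceTable:
    """Read a delimited abundance table.

    The file must have a header row and a leading label column.  No
    orientation guessing is done: the caller states whether rows are taxa
    (``taxa_rows``) or samples (``samples_rows``).  Rows with a duplicated
    taxon label are summed (profilers occasionally emit split genus rows);
    duplicated sample ids are an error.
    """
    path = Path(path)
    if orientation not in ("taxa_rows", "samples_rows"):
        raise ValueError("orientation must be 'taxa_rows' or 'samples_rows'")
    # check the raw header ourselves: pandas silently mangles duplicates
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(_sep_for(path))[1:]
    if orientation == "taxa_rows" and len(set(header)) != len(header):
        dup = sorted({h for h in header if header.count(h) > 1})
        raise ValueError(f"duplicate sample ids: {dup}")
    frame = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    if orientation == "samples_rows":
        frame = frame.T
        if frame.columns.duplicated().any():
            dup = sorted(set(frame.columns[frame.columns.duplicated()]))
            raise ValueError(f"duplicate sample ids: {dup}")
    vals = frame.to_numpy(dtype=float)
    neg = np.argwhere(vals < 0)
    if neg.size:
        i, j = neg[0]
        raise ValueError(
            f"negative count at taxon {frame.index[i]!r}, sample {frame.columns[j]!r}"
        )
    if frame.index.duplicated().any():
        frame = frame.groupby(level=0, sort=False).sum()
    return AbundanceTable.from_frame(frame)


def write_abundance_table(table: AbundanceTable, path: str | Path) -> None:
    """Write taxa x samples, TSV by suffix default, CSV for ``.csv``."""
    path = Path(path)
    table.to_frame().to_csv(path, sep=_sep_for(path), index_label="taxon",
                            float_format="%.6g")


# ---------------------------------------------------------------------------
# metadata / perfusion I/O

_BOOL_MAP = {"true": True, "false": False, "1": True, "0": False,
             "yes": True, "no": False}


def _coerce(value, target_type):
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    if target_type is bool:
        if isinstance(value, (bool, np.bool_)):
            return bool(value)
        return _BOOL_MAP[str(value).strip().lower()]
    return target_type(value)


def _records_from_csv(path: str | Path, cls, type_map: dict):
    frame = pd.read_csv(path)
    out = []
    for _, row in frame.iterrows():
        kwargs = {}
        for f in fields(cls):
            if f.name in frame.columns:
                kwargs[f.name] = _coerce(row[f.name], type_map.get(f.name, str))
        out.append(cls(**kwargs))
    return out


_META_TYPES = {"visit": int, "spo2": float, "age_days": float,
               "birth_weight_g": float, "gestational_age_wk": float,
               "maternal_antibiotics": bool, "gbs_colonization": bool}


def read_metadata(path: str | Path) -> list[SampleMetadata]:
    return _records_from_csv(path, SampleMetadata, _META_TYPES)


def write_metadata(meta: Iterable[SampleMetadata], path: str | Path) -> None:
    pd.DataFrame([vars(m) for m in meta]).to_csv(path, index=False)


_PERF_TYPES = {f.name: float for f in fields(PerfusionRecord)}
_PERF_TYPES["subject_id"] = str


def read_perfusion(path: str | Path) -> list[PerfusionRecord]:
    return _records_from_csv(path, PerfusionRecord, _PERF_TYPES)


def write_perfusion(records: Iterable[PerfusionRecord], path: str | Path) -> None:
    pd.DataFrame([vars(r) for r in records]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# replicate handling

def _sample_to_subject(table: AbundanceTable, meta: Sequence[SampleMetadata]) -> dict[str, SampleMetadata]:
    by_id = {m.sample_id: m for m in meta}
    unmapped = [s for s in table.samples if s not in by_id]
    if unmapped:
        raise KeyError(f"samples without metadata: {unmapped}")
    return {s: by_id[s] for s in table.samples}


def merge_replicates(table: AbundanceTable, meta: Sequence[SampleMetadata],
                     strategy: str = "mean_relative") -> AbundanceTable:
    """Collapse biological replicates to one column per subject.

    ``mean_relative`` closes each replicate to relative abundances, averages
    them and re-closes (the default: it treats replicates as equally
    informative compositions regardless of sequencing depth).  ``sum_counts``
    adds raw counts; ``first`` keeps the lowest visit index.
    """
    if strategy not in ("mean_relative", "sum_counts", "first"):
        raise ValueError(f"unknown strategy {strategy!r}")
    mapping = _sample_to_subject(table, meta)
    subjects: list[str] = []
    for s in table.samples:
        subj = mapping[s].subject_id
        if subj not in subjects:
            subjects.append(subj)
    cols = np.empty((len(table.taxa), len(subjects)))
    for j, subj in enumerate(subjects):
        ids = [s for s in table.samples if mapping[s].subject_id == subj]
        block = table.counts[:, [table.samples.index(s) for s in ids]]
        if strategy == "sum_counts":
            cols[:, j] = block.sum(axis=1)
        elif strategy == "first":
            visits = [mapping[s].visit for s in ids]
            cols[:, j] = block[:, int(np.argmin(visits))]
        else:
            sums = block.sum(axis=0)
            if np.any(sums <= 0):
                bad = [ids[k] for k in np.flatnonzero(sums <= 0)]
                raise ValueError(f"all-zero replicate(s) cannot be closed: {bad}")
            cols[:, j] = (block / sums).mean(axis=1)
    return AbundanceTable(list(table.taxa), subjects, cols)


def select_first_visit(table: AbundanceTable, meta: Sequence[SampleMetadata]) -> AbundanceTable:
    """Keep exactly one sample per subject: the minimum visit index.

    A subject with two samples at the same minimal visit is ambiguous and
    raises.
    """
    mapping = _sample_to_subject(table, meta)
    chosen: dict[str, str] = {}
    for s in table.samples:
        m = mapping[s]
        if m.subject_id not in chosen:
            chosen[m.subject_id] = s
        else:
            other = mapping[chosen[m.subject_id]]
            if m.visit < other.visit:
                chosen[m.subject_id] = s
            elif m.visit == other.visit:
                raise ValueError(
                    f"subject {m.subject_id!r} has two samples at visit {m.visit}"
                )
    keep = [s for s in table.samples if s in chosen.values()]
    return table.select_samples(keep)
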