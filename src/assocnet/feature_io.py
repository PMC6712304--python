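"""Reading, writing, binarizing and filtering feature abundance tables.

Two kinds of table flow through the pipeline, both features-by-samples:

* microbial tables (OTU or BGC-family counts), optionally with a trailing
  ``taxonomy`` column;
* molecular tables (LC-MS feature intensities), which must carry an ``mz``
  column (mass-to-charge, Thomson) and may carry a retention-time column.

Abundances are reduced to presence/absence sets ("a feature is present in a
sample when its abundance strictly exceeds a threshold"), the core object all
downstream statistics operate on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MICROBIAL = "microbial"
MOLECULAR = "molecular"
DECOY = "decoy"

#: header aliases (lower-cased) recognised as per-feature metadata columns
_MZ_ALIASES = {"mz", "m/z", "row m/z", "mass_to_charge"}
_RT_ALIASES = {"rt", "retention_time", "row retention time"}
_TAX_ALIASES = {"taxonomy", "taxon", "lineage"}
_ANNOT_ALIASES = {"annotation"}


@dataclass
class FeatureTable:
    """A named abundance matrix (features x samples) with per-feature metadata.

    Parameters
    ----------
    data:
        Non-negative abundances; index = feature ids, columns = sample ids.
        Counts for microbial tables, intensities for molecular tables.
    kind:
        ``"microbial"`` or ``"molecular"``.
    meta:
        Per-feature metadata aligned with ``data.index``.  Molecular tables
        carry an ``mz`` column (finite, > 0); microbial tables may carry
        ``taxonomy``.
    sep:
        Field separator the table was read with; writing uses the same one.
    """

    data: pd.DataFrame
    kind: str
    meta: pd.DataFrame = None
    sep: str = "\t"

    def __post_init__(self) -> None:
        if self.kind not in (MICROBIAL, MOLECULAR):
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.meta is None:
            self.meta = pd.DataFrame(index=self.data.index)
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].tolist()
            raise ValueError(f"duplicate feature ids: {dups[:5]}")
        if self.data.columns.duplicated().any():
            dups = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dups[:5]}")
        vals = self.data.to_numpy(dtype=float)
        if not np.isfinite(vals).all() or (vals < 0).any():
            raise ValueError("abundance values must be finite and >= 0")
        if not self.meta.index.equals(self.data.index):
            raise ValueError("metadata index does not match feature ids")
        if self.kind == MOLECULAR:
            if "mz" not in self.meta.columns:
                raise ValueError("molecular table lacks an mz column")
            mz = self.meta["mz"].to_numpy(dtype=float)
            if not (np.isfinite(mz).all() and (mz > 0).all()):
                raise ValueError("every molecular feature needs finite mz > 0")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_samples(self, samples: list[str]) -> "FeatureTable":
        return replace(self, data=self.data.loc[:, list(samples)])


@dataclass(frozen=True)
class BinaryFeature:
    """A feature reduced to its sample-presence set.

    ``sample_set`` is the set of samples in which the feature's abundance
    exceeded the binarization threshold.
    """

    feature_id: str
    sample_set: frozenset
    kind: str = MICROBIAL
    mz: float | None = None

    @property
    def prevalence(self) -> int:
        return len(self.sample_set)


@dataclass
class BinaryDataset:
    """Paired presence/absence data over one sample universe."""

    samples: tuple
    molecules: list
    microbes: list = field(default_factory=list)

    def __post_init__(self) -> None:
        universe = set(self.samples)
        if len(universe) != len(self.samples):
            raise ValueError("duplicate sample ids in universe")
        for side in (self.molecules, self.microbes):
            ids = [f.feature_id for f in side]
            if len(set(ids)) != len(ids):
                raise ValueError("duplicate feature ids within one side")
            for f in side:
                if not f.sample_set <= universe:
                    raise ValueError(
                        f"{f.feature_id}: sample_set not within the universe"
                    )

    @property
    def n_samples(self) -> int:
        return len(self.samples)


def _sep_for(path: str) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_feature_table(path, kind: str, dialect: str = "auto") -> FeatureTable:
    """Read a TSV/CSV feature-by-sample matrix.

    The first column holds feature ids and the header row holds sample ids.
    Recognised metadata columns (``mz``, ``rt``, ``taxonomy``, ``annotation``,
    case-insensitive) are split out of the matrix.  Empty cells and NaNs are
    treated as 0 (feature extractors emit blank/0 interchangeably for
    undetected features); any other non-numeric cell is a hard error naming
    the offending feature and sample.
    """
    if dialect not in ("auto", "matrix", "otu", "molecular"):
        raise ValueError(f"unknown dialect {dialect!r}")
    sep = _sep_for(path)
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    raw.index = raw.index.astype(str)

    meta = pd.DataFrame(index=raw.index)
    sample_cols = []
    for col in raw.columns:
        low = str(col).strip().lower()
        if low in _MZ_ALIASES:
            meta["mz"] = pd.to_numeric(raw[col], errors="raise")
        elif low in _RT_ALIASES:
            meta["rt"] = pd.to_numeric(raw[col], errors="raise")
        elif low in _TAX_ALIASES:
            meta["taxonomy"] = raw[col].fillna("")
        elif low in _ANNOT_ALIASES:
            meta["annotation"] = raw[col].fillna("")
        else:
            sample_cols.append(col)

    values = pd.DataFrame(index=raw.index, columns=sample_cols, dtype=float)
    for col in sample_cols:
        cells = raw[col].fillna("").str.strip().replace("", "0")
        num = pd.to_numeric(cells, errors="coerce")
        if num.isna().any():
            fid = num.index[num.isna()][0]
            raise ValueError(
                f"non-numeric value {raw.loc[fid, col]!r} for feature "
                f"{fid!r} in sample {col!r}"
            )
        values[col] = num.astype(float)
    values.columns = [str(c) for c in sample_cols]

    return FeatureTable(data=values, kind=kind, meta=meta, sep=sep)


def write_feature_table(table: FeatureTable, path) -> None:
    """Write a table back in the dialect it was read with.

    Molecular metadata (mz, rt) leads the sample columns; taxonomy/annotation
    trail them, mirroring the common OTU-table layout.
    """
    out = table.data.copy()
    for col in ("rt", "mz"):
        if col in table.meta.columns:
            out.insert(0, col, table.meta[col])
    for col in ("taxonomy", "annotation"):
        if col in table.meta.columns:
            out[col] = table.meta[col]
    out.index.name = table.data.index.name or "feature_id"
    out.to_csv(path, sep=table.sep)


def binarize(table: FeatureTable, threshold: float) -> list:
    """Reduce abundances to presence sets: present iff value > threshold.

    The inequality is strict, so a zero count is absent even at threshold 0
    (the MinCount = 0 convention for OTU tables).
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    mask = table.data.to_numpy(dtype=float) > threshold
    samples = np.asarray(table.sample_ids, dtype=object)
    mz = table.meta["mz"] if "mz" in table.meta.columns else None
    out = []
    for i, fid in enumerate(table.feature_ids):
        out.append(
            BinaryFeature(
                feature_id=str(fid),
                sample_set=frozenset(samples[mask[i]]),
                kind=table.kind,
                mz=float(mz.loc[fid]) if mz is not None else None,
            )
        )
    return out


def filter_prevalence(features: list, min_samples: int) -> list:
    """Keep features present in at least ``min_samples`` samples (order kept).

    The pipeline drops molecular features seen in fewer than two samples and
    rare BGC families seen in fewer than ten.
    """
    if min_samples < 0:
        raise ValueError("min_samples must be >= 0")
    return [f for f in features if len(f.sample_set) >= min_samples]


def align_samples(
    microbial: FeatureTable, molecular: FeatureTable
) -> tuple[FeatureTable, FeatureTable, tuple]:
    """Restrict both tables to their common samples.

    The statistics assume paired data; samples present in only one modality
    are dropped with a warning.  The kept order follows the microbial table.
    """
    common = [s for s in microbial.sample_ids if s in set(molecular.sample_ids)]
    dropped = (len(microbial.sample_ids) - len(common)) + (
        len(molecular.sample_ids) - len(common)
    )
    if not common:
        raise ValueError("the two tables share no sample ids")
    if dropped:
        logger.warning(
            "dropping %d unpaired sample columns (universe = %d shared samples)",
            dropped,
            len(common),
        )
    return microbial.subset_samples(common), molecular.subset_samples(common), tuple(common)


def make_binary_dataset(
    microbial: FeatureTable,
    molecular: FeatureTable,
    min_count: float = 0,
    min_intensity: float = 0,
    min_molecule_samples: int = 2,
    min_microbe_samples: int = 0,
) -> BinaryDataset:
    """Binarize a paired pair of tables into one :class:`BinaryDataset`.

    Applies the standard thresholds (MinCount for counts, MinIntensity for
    intensities) and the prevalence filters, over the intersection of the two
    tables' samples.
    """
    microbial, molecular, samples = align_samples(microbial, molecular)
    microbes = filter_prevalence(binarize(microbial, min_count), min_microbe_samples)
    molecules = filter_prevalence(
        binarize(molecular, min_intensity), min_molecule_samples
    )
    return BinaryDataset(samples=samples, molecules=molecules, microbes=microbes)
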