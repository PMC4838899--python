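"""Shared domain types for the multi-omics subtyping pipeline.

The pipeline exchanges a small number of tabular objects between stages:

* :class:`OmicsMatrix` — a features × samples real-valued matrix (log-scale
  expression, normalized miRNA abundance, or methylation beta values) with
  optional per-feature genomic annotation.
* class partitions — per-sample class labels carried as a ``pd.Series``
  (sample id → label, ``NaN`` allowed for "not classified at this level");
  :func:`validate_partition` enforces the contract.
* :class:`GNLTable` — discretized copy-number state (gain/normal/loss), either
  as genomic segments or as gene-level calls.
* sample annotations — a ``pd.DataFrame`` indexed by sample id with clinical
  columns (grade, IDH status, survival time/event, radiotherapy flag, normal
  control flag); :func:`validate_sample_annot` enforces the contract.
* :class:`GeneSet` — a named list of gene identifiers.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

OMIC_KINDS = ("mrna", "mirna", "methylation")

#: Allowed gain/normal/loss codes: -2 homozygous deletion, -1 loss, 0 neutral,
#: 1 gain, 2 amplification.
GNL_ALPHABET = (-2, -1, 0, 1, 2)


class FormatError(ValueError):
    """Malformed input file (duplicate ids, bad header, unparsable cell)."""


class ValidationError(ValueError):
    """Well-formed input violating a domain invariant."""


class ConfigError(ValueError):
    """Invalid configuration for the synthetic cohort generator."""


@lru_cache(maxsize=1)
def load_arm_table() -> pd.DataFrame:
    """hg19 chromosome-arm boundaries (1-based inclusive coordinates).

    Returns a frame with columns ``chrom``, ``arm``, ``start``, ``end``.
    Acrocentric p arms (13p, 14p, 15p, 21p, 22p) are excluded, leaving the
    39 autosomal arms plus Xp/Xq.
    """
    ref = importlib.resources.files("otomics").joinpath("data/hg19_arms.tsv")
    with ref.open() as fh:
        tab = pd.read_csv(fh, sep="\t", dtype={"chrom": str})
    return tab


def arm_vocabulary() -> frozenset[str]:
    return frozenset(load_arm_table()["arm"])


def _check_unique(ids: Iterable[str], what: str) -> None:
    idx = pd.Index(ids)
    if idx.has_duplicates:
        dups = idx[idx.duplicated()].unique().tolist()
        raise FormatError(f"duplicate {what}: {dups[:5]}")


@dataclass
class OmicsMatrix:
    """Features × samples matrix with optional per-feature annotation.

    ``values`` rows are features, columns samples. ``feature_annot`` (when
    given) is indexed like ``values`` and may carry ``chrom``, ``start``,
    ``end``, ``arm`` and ``cpg_island`` columns.
    """

    values: pd.DataFrame
    omic_kind: str
    feature_annot: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.omic_kind not in OMIC_KINDS:
            raise ValidationError(
                f"omic_kind must be one of {OMIC_KINDS}, got {self.omic_kind!r}"
            )
        _check_unique(self.values.index, "feature ids")
        _check_unique(self.values.columns, "sample ids")
        if self.omic_kind == "methylation":
            vals = self.values.to_numpy(dtype=float)
            bad = (vals < 0) | (vals > 1)
            if np.any(bad & ~np.isnan(vals)):
                i, j = np.argwhere(bad & ~np.isnan(vals))[0]
                raise ValidationError(
                    "methylation beta outside [0,1] at feature "
                    f"{self.values.index[i]!r}, sample {self.values.columns[j]!r}: "
                    f"{vals[i, j]}"
                )
        if self.feature_annot is not None:
            missing = self.values.index.difference(self.feature_annot.index)
            if len(missing):
                raise ValidationError(
                    f"feature_annot missing {len(missing)} features, e.g. {list(missing[:3])}"
                )
            self.feature_annot = self.feature_annot.loc[self.values.index]
            if "arm" in self.feature_annot.columns:
                arms = set(self.feature_annot["arm"].dropna())
                unknown = arms - arm_vocabulary()
                if unknown:
                    raise ValidationError(f"unknown arm labels: {sorted(unknown)[:5]}")

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def subset_samples(self, samples: Sequence[str]) -> "OmicsMatrix":
        return OmicsMatrix(self.values[list(samples)], self.omic_kind, self.feature_annot)


def validate_partition(labels: pd.Series, *, min_classes: int = 2) -> pd.Series:
    """Validate a class partition (sample id → label, NaN = unclassified)."""
    _check_unique(labels.index, "sample ids")
    observed = labels.dropna().unique()
    if len(observed) < min_classes:
        raise ValidationError(
            f"partition has {len(observed)} non-NA classes; need >= {min_classes}"
        )
    return labels


@dataclass
class GNLTable:
    """Gain/normal/loss copy-number calls.

    ``mode == "segment"``: ``segments`` has columns ``sample``, ``chrom``,
    ``start``, ``end``, ``gnl`` with 1-based inclusive coordinates and
    non-overlapping segments per (sample, chromosome).
    ``mode == "gene"``: ``genes`` is a gene × sample integer frame.
    """

    mode: str
    segments: pd.DataFrame | None = None
    genes: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.mode == "segment":
            seg = self.segments
            if seg is None:
                raise ValidationError("segment-mode GNLTable needs segments")
            bad = ~seg["gnl"].isin(GNL_ALPHABET)
            if bad.any():
                raise ValidationError(
                    f"gnl values outside {GNL_ALPHABET}: {seg.loc[bad, 'gnl'].unique()[:5]}"
                )
            if (seg["end"] < seg["start"]).any():
                raise ValidationError("segment with end < start")
            for (sample, chrom), grp in seg.groupby(["sample", "chrom"], sort=False):
                g = grp.sort_values("start")
                overlap = g["start"].to_numpy()[1:] <= g["end"].to_numpy()[:-1]
                if overlap.any():
                    raise ValidationError(
                        f"overlapping segments for sample {sample!r} chrom {chrom!r}"
                    )
        elif self.mode == "gene":
            if self.genes is None:
                raise ValidationError("gene-mode GNLTable needs genes frame")
            vals = self.genes.to_numpy()
            ok = np.isin(vals, GNL_ALPHABET) | pd.isna(vals)
            if not ok.all():
                raise ValidationError("gene-level gnl values outside alphabet")
            _check_unique(self.genes.index, "gene ids")
            _check_unique(self.genes.columns, "sample ids")
        else:
            raise ValidationError(f"unknown GNLTable mode {self.mode!r}")

    @property
    def sample_ids(self) -> list[str]:
        if self.mode == "segment":
            return list(pd.unique(self.segments["sample"]))
        return list(self.genes.columns)


SAMPLE_ANNOT_COLUMNS = [
    "cohort",
    "grade",
    "histology",
    "idh_status",
    "codel_status",
    "age",
    "os_time",
    "os_event",
    "initial_radiotherapy",
    "is_normal_control",
]


def validate_sample_annot(annot: pd.DataFrame) -> pd.DataFrame:
    _check_unique(annot.index, "sample ids")
    if "os_time" in annot:
        t = annot["os_time"].dropna()
        if (t < 0).any():
            raise ValidationError("os_time must be >= 0")
    if "os_event" in annot:
        e = annot["os_event"].dropna()
        if not e.isin([0, 1, True, False]).all():
            raise ValidationError("os_event must be 0/1")
    return annot


@dataclass(frozen=True)
class GeneSet:
    """Named gene list (e.g. a MYC target list) with a provenance tag."""

    name: str
    genes: tuple[str, ...]
    source: str = ""

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            object.__setattr__(self, "genes", tuple(dict.fromkeys(self.genes)))

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)
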