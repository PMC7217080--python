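"""Construct records and hydrophobicity feature computation.

A construct is a chimeric capsid-protein sequence identified by the peptide
insert it carries and the insertion strategy used to place it.  The feature
of a construct under one hydrophobicity scale is the *sum* of per-residue
scale values over the variable window of the sequence — the constant N- and
C-terminal flanks shared by all constructs carry no class information and
are trimmed off before summing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from Bio import SeqIO

from .scales import HydrophobicityScale, ScaleLibrary, _AA_SET


class FeatureError(ValueError):
    """Base class for feature-computation problems."""


class WindowError(FeatureError):
    """The trim window is empty or the sequence is too short."""


class UnknownResidueError(FeatureError):
    """A residue without a scale value occurred inside the window."""


class UndefinedRatioError(FeatureError):
    """K/R ratio requested for a sequence with no arginine."""


class DatasetError(ValueError):
    """Metadata/sequence join or label problems."""


def strategy_letter(strategy_id: int) -> str:
    """Render strategy 1, 2, ... as the display labels A, B, ..."""
    return chr(ord("A") + strategy_id - 1)


@dataclass
class ConstructRecord:
    """One chimeric construct: sequence, stratum, and optional class label.

    ``label`` is 1 for soluble ("positive") and 0 for insoluble
    ("negative"); ``None`` when unknown (prediction-only records).
    """

    construct_id: str
    insert_id: int
    strategy_id: int
    sequence: str
    label: Optional[int] = None

    def __post_init__(self) -> None:
        if self.label is not None and self.label not in (0, 1):
            raise DatasetError(
                f"{self.construct_id}: label must be 0, 1 or absent, "
                f"got {self.label!r}")


@dataclass
class Dataset:
    """A collection of constructs over an insert x strategy grid."""

    records: list[ConstructRecord]
    n_inserts: int
    n_strategies: int

    def __post_init__(self) -> None:
        pairs = [(r.insert_id, r.strategy_id) for r in self.records]
        if len(set(pairs)) != len(pairs):
            raise DatasetError("duplicate (insert_id, strategy_id) pairs")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def construct_ids(self) -> list[str]:
        return [r.construct_id for r in self.records]

    def labels(self) -> np.ndarray:
        """Label vector; raises if any record is unlabeled."""
        if any(r.label is None for r in self.records):
            missing = [r.construct_id for r in self.records if r.label is None]
            raise DatasetError(f"unlabeled records: {missing[:5]}...")
        return np.array([r.label for r in self.records], dtype=int)

    @property
    def f_sol(self) -> float:
        """Fraction of soluble (class 1) observations."""
        y = self.labels()
        return float(y.mean())

    def subset(self, indices: Iterable[int]) -> "Dataset":
        recs = [self.records[i] for i in indices]
        return Dataset(recs, self.n_inserts, self.n_strategies)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "construct_id": [r.construct_id for r in self.records],
            "insert_id": [r.insert_id for r in self.records],
            "strategy_id": [r.strategy_id for r in self.records],
            "strategy": [strategy_letter(r.strategy_id) for r in self.records],
            "label": [r.label for r in self.records],
        })


@dataclass
class FeatureMatrix:
    """Construct x scale matrix of feature values with trim provenance."""

    frame: pd.DataFrame  # rows: construct_id, columns: scale ids
    trim_n: int
    trim_c: int

    @property
    def scale_ids(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def construct_ids(self) -> list[str]:
        return list(self.frame.index)

    def column(self, scale_id: str) -> np.ndarray:
        return self.frame[scale_id].to_numpy()

    def row(self, construct_id: str) -> pd.Series:
        return self.frame.loc[construct_id]


def read_constructs(fasta_path, meta_path) -> Dataset:
    """Join a FASTA of sequences with a metadata CSV into a :class:`Dataset`.

    The metadata CSV must have columns ``construct_id``, ``insert_id``,
    ``strategy_id`` and optionally ``label`` (0, 1, or empty).  Every
    metadata row must have a FASTA record with a matching id and vice versa.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in seqs:
            raise DatasetError(f"duplicate FASTA id {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    meta = pd.read_csv(meta_path)
    required = {"construct_id", "insert_id", "strategy_id"}
    if not required.issubset(meta.columns):
        raise DatasetError(
            f"metadata missing column(s) {sorted(required - set(meta.columns))}")
    meta_ids = meta["construct_id"].astype(str).tolist()
    unknown = [i for i in meta_ids if i not in seqs]
    if unknown:
        raise DatasetError(f"metadata ids absent from FASTA: {unknown}")
    orphans = [i for i in seqs if i not in set(meta_ids)]
    if orphans:
        raise DatasetError(f"FASTA ids absent from metadata: {orphans}")
    records = []
    for _, row in meta.iterrows():
        cid = str(row["construct_id"])
        label = None
        if "label" in meta.columns and pd.notna(row["label"]):
            raw = float(row["label"])
            if raw not in (0.0, 1.0):
                raise DatasetError(f"{cid}: label {row['label']!r} not in {{0,1}}")
            label = int(raw)
        records.append(ConstructRecord(
            construct_id=cid,
            insert_id=int(row["insert_id"]),
            strategy_id=int(row["strategy_id"]),
            sequence=seqs[cid],
            label=label))
    n_inserts = len({r.insert_id for r in records})
    n_strategies = len({r.strategy_id for r in records})
    return Dataset(records, n_inserts=n_inserts, n_strategies=n_strategies)


def compute_feature(seq: str, scale: HydrophobicityScale,
                    trim_n: int = 0, trim_c: int = 0,
                    unknown_aa: str = "error") -> float:
    """Summed scale value over the trimmed window of ``seq``.

    The window is residues ``trim_n + 1 .. len(seq) - trim_c`` (1-based,
    inclusive): the first ``trim_n`` and last ``trim_c`` residues are
    omitted.  ``unknown_aa`` controls residues without a scale value:
    ``"error"`` (default) raises, ``"zero"``/``"skip"`` contribute nothing.
    """
    if trim_n < 0 or trim_c < 0:
        raise WindowError("trim counts must be non-negative")
    window = seq[trim_n: len(seq) - trim_c if trim_c else len(seq)]
    if not window:
        raise WindowError(
            f"empty window: len(seq)={len(seq)}, trim_n={trim_n}, "
            f"trim_c={trim_c}")
    total = 0.0
    for aa in window:
        if aa in _AA_SET:
            total += scale.values[aa]
        elif unknown_aa == "error":
            raise UnknownResidueError(
                f"residue {aa!r} has no value in scale {scale.id!r}")
        elif unknown_aa not in ("zero", "skip"):
            raise ValueError(f"unknown_aa policy {unknown_aa!r}")
    return total


def build_feature_matrix(dataset: Dataset, library: ScaleLibrary,
                         trim_n: int = 0, trim_c: int = 0,
                         unknown_aa: str = "error") -> FeatureMatrix:
    """Feature matrix with one row per construct, one column per scale.

    Column order equals library order.  Errors from
    :func:`compute_feature` are re-raised with construct/scale context.
    """
    arrays = {}
    for scale in library:
        col = np.empty(len(dataset), dtype=float)
        for i, rec in enumerate(dataset):
            try:
                col[i] = compute_feature(rec.sequence, scale, trim_n, trim_c,
                                         unknown_aa=unknown_aa)
            except FeatureError as exc:
                raise type(exc)(
                    f"construct {rec.construct_id!r}, scale {scale.id!r}: "
                    f"{exc}") from exc
        arrays[scale.id] = col
    frame = pd.DataFrame(arrays, index=dataset.construct_ids)
    return FeatureMatrix(frame=frame, trim_n=trim_n, trim_c=trim_c)


def kr_ratio(seq: str) -> float:
    """Lysine-to-arginine count ratio of a sequence.

    Raises :class:`UndefinedRatioError` when the sequence contains no
    arginine (zero denominator).
    """
    if not seq:
        raise FeatureError("empty sequence")
    n_r = seq.count("R")
    if n_r == 0:
        raise UndefinedRatioError("sequence contains no arginine; K/R undefined")
    return seq.count("K") / n_r
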