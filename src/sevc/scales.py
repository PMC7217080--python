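"""Hydrophobicity scales: loading, normalization, orientation, and audits.

A hydrophobicity scale assigns one real number to each of the 20 canonical
amino acids.  Scales in a :class:`ScaleLibrary` are the raw material of the
ensemble classifier: each scale later becomes one feature and one decision
stump.  Before use, every scale is centered to mean zero and scaled to unit
variance, and its sign is oriented so that aspartic acid (D) is non-positive;
orientation makes "more hydrophobic" point the same way in every scale.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Canonical one-letter codes, fixed order used for arrays and CSV columns.
AMINO_ACIDS = ("A", "R", "N", "D", "C", "Q", "E", "G", "H", "I",
               "L", "K", "M", "F", "P", "S", "T", "W", "Y", "V")

_AA_SET = frozenset(AMINO_ACIDS)


class ScaleError(ValueError):
    """Base class for scale-related validation problems."""


class ScaleFormatError(ScaleError):
    """The scale table is structurally malformed (missing/unknown columns)."""


class ScaleParseError(ScaleError):
    """A cell of the scale table could not be parsed as a number."""


class ScaleValidationError(ScaleError):
    """Scale content violates an invariant (duplicate id, missing residue)."""


class DegenerateScaleError(ScaleError):
    """All 20 values identical: the scale has zero variance."""


@dataclass(frozen=True)
class HydrophobicityScale:
    """One hydrophobicity scale: 20 per-residue values plus an identifier.

    Parameters
    ----------
    id : str
        Short identifier, unique within a library.
    values : dict
        Mapping from each canonical one-letter code to a real value.
    normalized : bool
        True once the scale has been centered and scaled to unit variance.
    """

    id: str
    values: dict[str, float]
    normalized: bool = False

    def __post_init__(self) -> None:
        keys = set(self.values)
        if keys != _AA_SET:
            missing = sorted(_AA_SET - keys)
            extra = sorted(keys - _AA_SET)
            raise ScaleValidationError(
                f"scale {self.id!r}: expected exactly the 20 canonical amino "
                f"acids; missing {missing}, unexpected {extra}")
        arr = self.as_array()
        if not np.all(np.isfinite(arr)):
            raise ScaleValidationError(f"scale {self.id!r}: non-finite value")

    def as_array(self) -> np.ndarray:
        """Values as a float array in canonical :data:`AMINO_ACIDS` order."""
        return np.array([self.values[a] for a in AMINO_ACIDS], dtype=float)

    def __getitem__(self, residue: str) -> float:
        return self.values[residue]


def normalize_scale(scale: HydrophobicityScale) -> HydrophobicityScale:
    """Center to mean 0 and scale to unit variance.

    The population convention (divisor 20) is used: a scale enumerates all 20
    residues and is not a sample from a larger population.

    Raises
    ------
    DegenerateScaleError
        If all 20 values are identical (zero variance).
    """
    arr = scale.as_array()
    sd = arr.std()  # ddof=0, population convention
    if sd == 0.0:
        raise DegenerateScaleError(
            f"scale {scale.id!r} has zero variance; cannot normalize")
    z = (arr - arr.mean()) / sd
    return HydrophobicityScale(
        id=scale.id, values=dict(zip(AMINO_ACIDS, z.tolist())), normalized=True)


def orient_scale(scale: HydrophobicityScale) -> HydrophobicityScale:
    """Flip the scale's sign if aspartic acid is rated positive.

    After orientation ``value(D) <= 0`` in every scale, so hydrophilic,
    charged residues point the same way across the library.  Idempotent.
    """
    if scale.values["D"] <= 0:
        return scale
    flipped = {a: -v for a, v in scale.values.items()}
    return replace(scale, values=flipped)


def charge_scale() -> HydrophobicityScale:
    """The net-charge baseline "scale": D=E=-1, R=K=+1, all others 0.

    Used raw (un-normalized): summing it over a sequence window gives the
    window's net charge, the insert-charge baseline classifier's feature.
    """
    values = {a: 0.0 for a in AMINO_ACIDS}
    values["D"] = values["E"] = -1.0
    values["R"] = values["K"] = +1.0
    return HydrophobicityScale(id="charge", values=values, normalized=False)


@dataclass
class ScaleLibrary:
    """Ordered collection of scales with unique ids.

    Order is significant: it defines tie-breaking during feature selection
    and the column order of feature matrices.
    """

    scales: list[HydrophobicityScale]
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [s.id for s in self.scales]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ScaleValidationError(f"duplicate scale ids: {dupes}")

    def __len__(self) -> int:
        return len(self.scales)

    def __iter__(self):
        return iter(self.scales)

    def __getitem__(self, scale_id: str) -> HydrophobicityScale:
        for s in self.scales:
            if s.id == scale_id:
                return s
        raise KeyError(scale_id)

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.scales]

    def normalized(self) -> "ScaleLibrary":
        """New library with every scale normalized and oriented."""
        return ScaleLibrary(
            [orient_scale(normalize_scale(s)) for s in self.scales],
            provenance=dict(self.provenance))

    def exclude_reversed(self, atol: float = 1e-9) -> "ScaleLibrary":
        """Drop the later member of every exactly anti-correlated pair.

        Two scales are "reversed" copies of each other when their normalized
        values have Pearson correlation -1 (within ``atol``).  The library
        keeps the earlier scale of each pair, preserving order.
        """
        norm = [normalize_scale(s).as_array() for s in self.scales]
        keep: list[HydrophobicityScale] = []
        keep_arr: list[np.ndarray] = []
        for s, a in zip(self.scales, norm):
            # r == -1 after z-scoring <=> arrays are exact negations
            if any(np.allclose(a, -b, atol=atol) for b in keep_arr):
                continue
            keep.append(s)
            keep_arr.append(a)
        return ScaleLibrary(keep, provenance={
            k: v for k, v in self.provenance.items()
            if k in {s.id for s in keep}})


def read_scale_table(path) -> ScaleLibrary:
    """Read a scale table CSV (one row per scale) into a :class:`ScaleLibrary`.

    The file must have a ``scale_id`` column (or any first column holding the
    id) plus exactly the 20 canonical one-letter columns, in any order.
    Scales are returned un-normalized, in file order.
    """
    frame = pd.read_csv(path, dtype=str)
    cols = list(frame.columns)
    id_col = "scale_id" if "scale_id" in cols else cols[0]
    aa_cols = [c for c in cols if c != id_col]
    missing = sorted(_AA_SET - set(aa_cols))
    if missing:
        raise ScaleFormatError(
            f"{path}: missing amino-acid column(s) {missing}")
    unknown = sorted(set(aa_cols) - _AA_SET)
    if unknown:
        raise ScaleFormatError(
            f"{path}: unexpected column(s) {unknown}")
    scales = []
    for row_no, row in enumerate(frame.itertuples(index=False), start=2):
        record = dict(zip(cols, row))
        values = {}
        for aa in AMINO_ACIDS:
            cell = record[aa]
            try:
                values[aa] = float(cell)
            except (TypeError, ValueError):
                raise ScaleParseError(
                    f"{path}: row {row_no}, column {aa!r}: "
                    f"non-numeric cell {cell!r}") from None
        scales.append(HydrophobicityScale(id=str(record[id_col]), values=values))
    return ScaleLibrary(scales)


def load_fixture_library() -> ScaleLibrary:
    """Bundled fixture set of 10 well-known published hydrophobicity scales.

    Kyte-Doolittle, Hopp-Woods, the Eisenberg consensus, Fauchere-Pliska,
    Engelman (GES), Janin, Rose, the Wimley-White interface scale, the Hessa
    translocon scale, and Monera.  This is a small demonstration/fixture set,
    not the 91-scale collection used in the original solubility study.
    Returned un-normalized; call :meth:`ScaleLibrary.normalized` before use.
    """
    ref = importlib.resources.files("sevc.data") / "hydrophobicity_fixture.csv"
    with importlib.resources.as_file(ref) as path:
        return read_scale_table(path)


def scale_profile_stats(library: ScaleLibrary) -> pd.DataFrame:
    """Per-residue median and MAD of scale values across the library.

    MAD is the unscaled median absolute deviation,
    ``median(|x - median(x)|)``.  The library should already be normalized
    and oriented so values are comparable across scales.

    Returns
    -------
    pandas.DataFrame
        Indexed by residue in canonical order, columns ``median`` and ``mad``.
    """
    if len(library) == 0:
        raise ScaleValidationError("empty library: no profile statistics")
    mat = np.vstack([s.as_array() for s in library])  # scales x residues
    med = np.median(mat, axis=0)
    mad = np.median(np.abs(mat - med), axis=0)
    return pd.DataFrame({"median": med, "mad": mad}, index=list(AMINO_ACIDS))


def pca_variance_explained(library: ScaleLibrary) -> np.ndarray:
    """Variance-explained ratios of a PCA across the library's scales.

    The data matrix has the 20 amino acids as observations (rows) and the
    scales as variables (columns); each column is centered and the
    eigenvalues of the resulting covariance matrix are returned as
    descending fractions of total variance (summing to 1).  A first ratio
    near 1 means the scales are mutually redundant.
    """
    if len(library) < 2:
        raise ScaleValidationError("PCA requires at least 2 scales")
    x = np.column_stack([s.as_array() for s in library])  # 20 x n_scales
    x = x - x.mean(axis=0)
    cov = (x.T @ x) / (x.shape[0] - 1)
    eigvals = np.linalg.eigvalsh(cov)[::-1]
    eigvals = np.clip(eigvals, 0.0, None)
    return eigvals / eigvals.sum()
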