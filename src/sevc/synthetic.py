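"""Synthetic construct grids with the statistical structure of the study.

The real sequence set (chimeric capsid constructs over a 71-insert x
8-strategy grid) is confidential, so the generator emulates its structure:
every construct is a constant N-flank + a scaffold core edited by the
insertion strategy + a random peptide insert + a constant C-flank.  The
solubility label is a threshold on a latent hydrophobicity score

    latent = w_insert * feature(insert, true_scale)
           + w_strategy * feature(edited core, true_scale)

optionally corrupted by independent label noise.  Strategy effects are
realized as deterministic sequence edits (per-strategy insertion position,
deletion length, and for one designated "bad" strategy an arginine-rich
extra segment), so with the default weights (1, 1) the latent score equals
*exactly* the true scale's feature of the observable trimmed window —
making the noise-free grid perfectly separable by that feature, the anchor
every downstream recovery test builds on.  The default label threshold
sits in the widest latent-score gap near the median, which keeps the two
classes balanced and leaves a margin for finite-sample split thresholds to
generalize.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .features import ConstructRecord, Dataset, compute_feature, strategy_letter
from .scales import (AMINO_ACIDS, HydrophobicityScale, load_fixture_library,
                     normalize_scale, orient_scale)


class SyntheticConfigError(ValueError):
    pass


def default_true_scale() -> HydrophobicityScale:
    """Normalized, oriented Kyte-Doolittle scale from the bundled fixtures."""
    return orient_scale(normalize_scale(load_fixture_library()["KD"]))


@dataclass
class SyntheticConfig:
    """Generator settings; defaults mirror the emulated study grid.

    71 inserts x 8 strategies = 568 constructs, insert-dominant labels
    (peptide inserts of 15-25 residues dominate the latent score, strategy
    edits of a few residues perturb it weakly), label noise off by default.
    ``flip_strategy`` adversarially flips that strategy's labels with
    probability ``flip_prob`` (for misclassification-bias analyses).
    """

    n_inserts: int = 71
    n_strategies: int = 8
    insert_len_range: tuple[int, int] = (15, 25)
    core_len: int = 30
    trim_n: int = 73
    trim_c: int = 71
    true_scale: Optional[HydrophobicityScale] = None
    threshold: Optional[float] = None
    insert_effect_weight: float = 1.0
    strategy_effect_weight: float = 1.0
    label_noise: float = 0.0
    flip_strategy: Optional[int] = None
    flip_prob: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_inserts < 1 or self.n_strategies < 1:
            raise SyntheticConfigError("grid dimensions must be >= 1")
        lo, hi = self.insert_len_range
        if not (1 <= lo <= hi):
            raise SyntheticConfigError("invalid insert length range")
        if self.insert_effect_weight < 0 or self.strategy_effect_weight < 0:
            raise SyntheticConfigError("effect weights must be >= 0")
        if not (0.0 <= self.label_noise < 0.5):
            raise SyntheticConfigError("label_noise must be in [0, 0.5)")
        if not (0.0 <= self.flip_prob <= 1.0):
            raise SyntheticConfigError("flip_prob must be in [0, 1]")
        if self.core_len < 13:
            raise SyntheticConfigError("core_len must be >= 13")
        if self.trim_n < 0 or self.trim_c < 0:
            raise SyntheticConfigError("trim lengths must be >= 0")


@dataclass
class GroundTruth:
    """What the generator knows and a recovery test may check."""

    true_scale_id: str
    threshold: float
    latent: dict[str, float]
    strategy_offsets: dict[int, float]
    noise_flipped: list[str] = field(default_factory=list)
    adversarial_flipped: list[str] = field(default_factory=list)


def _random_peptide(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def _widest_central_gap(latent: np.ndarray) -> float:
    """Threshold in the widest gap within the central 10% of sorted scores.

    Staying between the 45th and 55th percentiles keeps the soluble
    fraction in [0.45, 0.55]; taking the widest gap there leaves a margin
    around the class boundary.
    """
    xs = np.sort(latent)
    n = xs.size
    lo = max(int(np.floor(0.45 * n)), 0)
    hi = min(int(np.floor(0.55 * n)), n - 1)
    if hi <= lo:
        return float(np.median(xs))
    gaps = np.diff(xs[lo:hi + 1])
    j = int(np.argmax(gaps))
    return float((xs[lo + j] + xs[lo + j + 1]) / 2.0)


def generate_dataset(cfg: SyntheticConfig) -> tuple[Dataset, GroundTruth]:
    """Generate the full insert x strategy grid plus its ground truth.

    Deterministic in ``cfg.seed``.  Labels: 1 (soluble) when the latent
    score is below the threshold (low hydrophobicity favors solubility),
    then independently flipped with probability ``label_noise``, then
    adversarially flipped for ``flip_strategy`` if configured.
    """
    rng = np.random.default_rng(cfg.seed)
    scale = cfg.true_scale if cfg.true_scale is not None else default_true_scale()

    n_flank = _random_peptide(rng, cfg.trim_n) if cfg.trim_n else ""
    c_flank = _random_peptide(rng, cfg.trim_c) if cfg.trim_c else ""
    core = _random_peptide(rng, cfg.core_len)

    # per-strategy deterministic edits: insertion position, deletion, extra
    positions = rng.integers(4, cfg.core_len - 8, size=cfg.n_strategies)
    deletions = rng.integers(0, 5, size=cfg.n_strategies)
    extras = [""] * cfg.n_strategies
    extras[-1] = "RRRR"  # designated "bad" strategy: arginine-rich edit

    edited_cores = []
    offsets = {}
    for s in range(cfg.n_strategies):
        pre = core[: positions[s]] + extras[s]
        post = core[positions[s] + deletions[s]:]
        edited_cores.append((pre, post))
        offsets[s + 1] = compute_feature(pre + post, scale)

    inserts = [_random_peptide(rng, int(rng.integers(
        cfg.insert_len_range[0], cfg.insert_len_range[1] + 1)))
        for _ in range(cfg.n_inserts)]
    insert_feats = [compute_feature(pep, scale) for pep in inserts]

    records: list[ConstructRecord] = []
    latent: dict[str, float] = {}
    for i in range(cfg.n_inserts):
        for s in range(cfg.n_strategies):
            cid = f"I{i + 1:03d}{strategy_letter(s + 1)}"
            pre, post = edited_cores[s]
            seq = n_flank + pre + inserts[i] + post + c_flank
            records.append(ConstructRecord(
                construct_id=cid, insert_id=i + 1, strategy_id=s + 1,
                sequence=seq))
            latent[cid] = (cfg.insert_effect_weight * insert_feats[i]
                           + cfg.strategy_effect_weight * offsets[s + 1])

    scores = np.array([latent[r.construct_id] for r in records])
    threshold = (cfg.threshold if cfg.threshold is not None
                 else _widest_central_gap(scores))

    labels = (scores < threshold).astype(int)
    noise_flipped: list[str] = []
    if cfg.label_noise > 0:
        flip = rng.random(len(records)) < cfg.label_noise
        labels[flip] ^= 1
        noise_flipped = [records[i].construct_id
                         for i in np.nonzero(flip)[0]]
    adversarial: list[str] = []
    if cfg.flip_strategy is not None:
        for i, rec in enumerate(records):
            if rec.strategy_id == cfg.flip_strategy and (
                    rng.random() < cfg.flip_prob):
                labels[i] ^= 1
                adversarial.append(rec.construct_id)
    for rec, lab in zip(records, labels):
        rec.label = int(lab)

    ds = Dataset(records, n_inserts=cfg.n_inserts,
                 n_strategies=cfg.n_strategies)
    truth = GroundTruth(
        true_scale_id=scale.id, threshold=float(threshold), latent=latent,
        strategy_offsets=offsets, noise_flipped=noise_flipped,
        adversarial_flipped=adversarial)
    return ds, truth


def write_fasta(ds: Dataset, path) -> None:
    """Write construct sequences as uncompressed FASTA."""
    with open(path, "w") as fh:
        for rec in ds:
            fh.write(f">{rec.construct_id}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i:i + 60] + "\n")


def write_metadata(ds: Dataset, path) -> None:
    """Write the metadata/label CSV consumed by :func:`read_constructs`."""
    ds.to_frame().drop(columns=["strategy"]).to_csv(path, index=False)
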