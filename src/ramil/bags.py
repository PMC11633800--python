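"""Bag data model, manifest I/O, and synthetic witness-bag generators.

A *bag* is one patient's ordered sequence of K two-dimensional slices with a
single binary label; individual slice (instance) labels are unobserved during
training. The synthetic generators create bags in which positive bags carry
exactly ``m_witnesses`` discriminative instances ("witnesses") at known
positions, so every downstream stage — attention scoring, top-C selection,
training, interpretability — can be evaluated against ground truth that real
clinical data cannot provide.

Two synthetic modes are offered:

``feature_space``
    Instances are L-dimensional feature vectors. Background instances are
    i.i.d. spherical Gaussian with standard deviation ``noise_sd``; witness
    instances have their mean shifted by ``effect_size`` along a fixed unit
    signal direction (``ones(L)/sqrt(L)``, so train/test sets generated with
    different seeds share the same signal).

``image``
    Instances are 224×224 grayscale slices of clipped Gaussian background
    noise; witness slices additionally contain a bright Gaussian blob at a
    random location with peak amplitude proportional to ``effect_size``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from PIL import Image

logger = logging.getLogger(__name__)

IMAGE_SIZE = 224
BACKGROUND_LEVEL = 0.2
BLOB_SIGMA = 12.0
BLOB_PEAK_PER_EFFECT = 0.25  # blob peak amplitude = effect_size * this


class InvalidSpecError(ValueError):
    """Raised when a synthetic-data spec is internally inconsistent."""


@dataclass
class Bag:
    """One patient's ordered slice sequence plus its binary label.

    Slice order is acquisition order and is preserved by every operation;
    index ``k`` (0-based internally, 1-based in reports) identifies a slice.
    """

    patient_id: str
    slices: np.ndarray  # (K, H, W), values in [0, 1]
    label: int

    def __post_init__(self) -> None:
        self.slices = np.asarray(self.slices, dtype=float)
        if self.slices.ndim != 3 or self.slices.shape[0] < 1:
            raise ValueError("slices must be a (K, H, W) array with K >= 1")
        if int(self.label) not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")
        self.label = int(self.label)

    @property
    def K(self) -> int:
        return self.slices.shape[0]


@dataclass
class SyntheticBag:
    """A Bag with ground-truth per-instance witness flags (for evaluation only)."""

    bag: Bag
    witness_flags: np.ndarray  # (K,) in {0, 1}
    spec_id: str = ""

    def __post_init__(self) -> None:
        self.witness_flags = np.asarray(self.witness_flags, dtype=int)
        if self.witness_flags.shape != (self.bag.K,):
            raise ValueError("witness_flags must have one entry per slice")
        if self.bag.label != int(self.witness_flags.max(initial=0) > 0):
            raise ValueError("bag label must equal max(witness_flags)")


class FeatureBag(NamedTuple):
    """A feature-space synthetic bag: K×L instance features plus ground truth."""

    features: np.ndarray  # (K, L)
    label: int
    witness_flags: np.ndarray  # (K,)
    patient_id: str


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic witness-bag dataset.

    ``effect_size`` is the mean shift (feature mode) or blob-amplitude scale
    (image mode) carried by witness instances; ``effect_size = 0`` makes
    positive and negative bags distributionally identical.
    """

    n_bags: int
    positive_fraction: float
    K: int
    m_witnesses: int
    effect_size: float
    noise_sd: float = 1.0
    mode: str = "feature_space"
    L: int = 32
    seed: int = 0
    witness_placement: str = "uniform"  # or "centered"

    def __post_init__(self) -> None:
        if self.mode not in ("feature_space", "image"):
            raise InvalidSpecError(f"unknown mode {self.mode!r}")
        if self.n_bags < 2:
            raise InvalidSpecError("n_bags must be at least 2")
        if not 0.0 <= self.positive_fraction <= 1.0:
            raise InvalidSpecError("positive_fraction must be in [0, 1]")
        if self.K < 1:
            raise InvalidSpecError("K must be >= 1")
        if self.m_witnesses > self.K:
            raise InvalidSpecError(
                f"m_witnesses ({self.m_witnesses}) cannot exceed K ({self.K})"
            )
        if self.positive_fraction > 0 and self.m_witnesses < 1:
            raise InvalidSpecError("positive bags require m_witnesses >= 1")
        if self.noise_sd <= 0:
            raise InvalidSpecError("noise_sd must be positive")
        if self.effect_size < 0:
            raise InvalidSpecError("effect_size must be nonnegative")
        if self.witness_placement not in ("uniform", "centered"):
            raise InvalidSpecError(f"unknown witness_placement {self.witness_placement!r}")

    @property
    def n_positive(self) -> int:
        return int(round(self.n_bags * self.positive_fraction))

    @property
    def spec_id(self) -> str:
        return (
            f"{self.mode}-n{self.n_bags}-p{self.positive_fraction}-K{self.K}"
            f"-m{self.m_witnesses}-e{self.effect_size}-s{self.noise_sd}-seed{self.seed}"
        )


def signal_direction(L: int) -> np.ndarray:
    """Fixed unit signal direction shared by every feature-space dataset of width L."""
    return np.ones(L) / np.sqrt(L)


def _labels_and_witnesses(spec: SyntheticSpec, rng: np.random.Generator):
    """Assign bag labels (exact positive count) and witness positions."""
    labels = np.zeros(spec.n_bags, dtype=int)
    labels[: spec.n_positive] = 1
    rng.shuffle(labels)
    witness_sets = []
    k_idx = np.arange(spec.K)
    if spec.witness_placement == "centered":
        center = (spec.K - 1) / 2.0
        weights = np.exp(-0.5 * ((k_idx - center) / max(spec.K / 6.0, 1.0)) ** 2)
        p = weights / weights.sum()
    else:
        p = None
    for y in labels:
        if y:
            witness_sets.append(
                np.sort(rng.choice(spec.K, size=spec.m_witnesses, replace=False, p=p))
            )
        else:
            witness_sets.append(np.empty(0, dtype=int))
    return labels, witness_sets


def generate_feature_bags(spec: SyntheticSpec) -> list[FeatureBag]:
    """Generate feature-space witness bags.

    Negative-bag instances are i.i.d. N(0, noise_sd² I) in R^L; in positive
    bags exactly ``m_witnesses`` instances, at positions drawn per
    ``witness_placement``, have mean shifted by ``effect_size`` along the
    fixed signal direction. Identical spec (including seed) reproduces the
    arrays bit for bit.
    """
    if spec.mode != "feature_space":
        raise InvalidSpecError("generate_feature_bags requires mode='feature_space'")
    rng = np.random.default_rng(spec.seed)
    labels, witness_sets = _labels_and_witnesses(spec, rng)
    direction = signal_direction(spec.L)
    bags: list[FeatureBag] = []
    for i, (y, wit) in enumerate(zip(labels, witness_sets)):
        X = rng.normal(0.0, spec.noise_sd, size=(spec.K, spec.L))
        flags = np.zeros(spec.K, dtype=int)
        if y:
            X[wit] += spec.effect_size * direction
            flags[wit] = 1
        bags.append(FeatureBag(X, int(y), flags, f"synth{i:04d}"))
    return bags


def _gaussian_blob(size: int, center: tuple[float, float], sigma: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    r2 = (yy - center[0]) ** 2 + (xx - center[1]) ** 2
    return np.exp(-0.5 * r2 / sigma**2)


def generate_image_bags(spec: SyntheticSpec) -> list[SyntheticBag]:
    """Generate image-mode witness bags of 224×224 slices.

    Every slice is clipped Gaussian background noise around a constant gray
    level; witness slices additionally carry a bright Gaussian blob (peak
    amplitude ``BLOB_PEAK_PER_EFFECT * effect_size``, width ``BLOB_SIGMA``)
    at a uniformly random interior location. Blob centers are recorded in
    bag-level metadata via :func:`blob_centers_of`.
    """
    if spec.mode != "image":
        raise InvalidSpecError("generate_image_bags requires mode='image'")
    rng = np.random.default_rng(spec.seed)
    labels, witness_sets = _labels_and_witnesses(spec, rng)
    peak = BLOB_PEAK_PER_EFFECT * spec.effect_size
    margin = int(3 * BLOB_SIGMA)
    out: list[SyntheticBag] = []
    for i, (y, wit) in enumerate(zip(labels, witness_sets)):
        slices = BACKGROUND_LEVEL + rng.normal(0.0, spec.noise_sd, size=(spec.K, IMAGE_SIZE, IMAGE_SIZE))
        flags = np.zeros(spec.K, dtype=int)
        centers: dict[int, tuple[float, float]] = {}
        for k in wit:
            cy, cx = rng.uniform(margin, IMAGE_SIZE - margin, size=2)
            slices[k] += peak * _gaussian_blob(IMAGE_SIZE, (cy, cx), BLOB_SIGMA)
            flags[k] = 1
            centers[int(k)] = (float(cy), float(cx))
        np.clip(slices, 0.0, 1.0, out=slices)
        bag = Bag(patient_id=f"synth{i:04d}", slices=slices, label=int(y))
        sb = SyntheticBag(bag=bag, witness_flags=flags, spec_id=spec.spec_id)
        sb.blob_centers = centers  # type: ignore[attr-defined]
        out.append(sb)
    return out


def blob_centers_of(sbag: SyntheticBag) -> dict[int, tuple[float, float]]:
    """Ground-truth blob centers keyed by 0-based slice index (empty for negatives)."""
    return getattr(sbag, "blob_centers", {})


# ---------------------------------------------------------------------------
# manifest and on-disk formats


def write_manifest(records: Iterable[tuple[str, str, int]], path: str | Path) -> None:
    """Write a patient-level manifest CSV with columns patient_id, label, slice_dir."""
    rows = [
        {"patient_id": pid, "label": int(label), "slice_dir": str(sdir)}
        for pid, sdir, label in records
    ]
    pd.DataFrame(rows, columns=["patient_id", "label", "slice_dir"]).to_csv(path, index=False)


def read_manifest(path: str | Path) -> list[tuple[str, str, int]]:
    """Read a manifest CSV; returns (patient_id, slice_dir, label) triples.

    Labels must be binary; duplicate patient ids are an error; an empty
    manifest yields an empty list with a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    df = pd.read_csv(path)
    required = {"patient_id", "label", "slice_dir"}
    if not required.issubset(df.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    if df.empty:
        logger.warning("manifest %s is empty", path)
        return []
    if df["patient_id"].duplicated().any():
        dups = df.loc[df["patient_id"].duplicated(), "patient_id"].tolist()
        raise ValueError(f"duplicate patient_id entries: {dups}")
    labels = df["label"].to_numpy()
    if not np.isin(labels, (0, 1)).all():
        bad = sorted(set(labels) - {0, 1})
        raise ValueError(f"labels must be 0 or 1; found {bad}")
    return [
        (str(r.patient_id), str(r.slice_dir), int(r.label)) for r in df.itertuples()
    ]


def save_image_bags(bags: Sequence[SyntheticBag | Bag], out_dir: str | Path) -> Path:
    """Write bags as per-patient PNG slice directories plus a manifest CSV.

    Returns the manifest path. Slices are saved as 16-bit grayscale PNGs
    named ``slice_###.png`` in acquisition order.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = []
    for item in bags:
        bag = item.bag if isinstance(item, SyntheticBag) else item
        sdir = out_dir / bag.patient_id
        sdir.mkdir(exist_ok=True)
        for k in range(bag.K):
            arr = np.clip(bag.slices[k], 0.0, 1.0)
            Image.fromarray((arr * 65535).astype(np.uint16)).save(
                sdir / f"slice_{k + 1:03d}.png"
            )
        records.append((bag.patient_id, bag.patient_id, bag.label))
    manifest = out_dir / "manifest.csv"
    write_manifest(records, manifest)
    return manifest


def load_image_bags(manifest_path: str | Path) -> list[Bag]:
    """Load bags from a manifest CSV; slice_dir paths are relative to the manifest."""
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    bags = []
    for pid, sdir, label in read_manifest(manifest_path):
        files = sorted((root / sdir).glob("slice_*.png"))
        if not files:
            raise FileNotFoundError(f"no slices found for patient {pid} in {root / sdir}")
        slices = np.stack(
            [np.asarray(Image.open(f), dtype=float) / 65535.0 for f in files]
        )
        bags.append(Bag(patient_id=pid, slices=slices, label=label))
    return bags


def save_feature_bags(bags: Sequence[FeatureBag], path: str | Path) -> None:
    """Persist feature bags as an NPZ archive (one array per bag plus metadata)."""
    arrays = {f"features_{i}": b.features for i, b in enumerate(bags)}
    arrays.update({f"flags_{i}": b.witness_flags for i, b in enumerate(bags)})
    arrays["labels"] = np.array([b.label for b in bags])
    arrays["patient_ids"] = np.array([b.patient_id for b in bags])
    np.savez_compressed(path, **arrays)


def load_feature_bags(path: str | Path) -> list[FeatureBag]:
    with np.load(path, allow_pickle=False) as z:
        labels = z["labels"]
        pids = z["patient_ids"]
        return [
            FeatureBag(z[f"features_{i}"], int(labels[i]), z[f"flags_{i}"], str(pids[i]))
            for i in range(len(labels))
        ]
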