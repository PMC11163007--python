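"""Data model, I/O and preprocessing for labeled one-dimensional spectra.

The unit of analysis is a phase-angle (or intensity) spectrum: an ordered
sequence of real sensor measurements with a categorical phase label such as
``"solution"`` or ``"gel"``.  Because repeated experiments use different
sensors with different frequency windows, the frequency axis carries no
shared meaning across experiments; spectra are therefore re-indexed onto the
plain measurement sequence 1..N before any learning step
(:func:`to_sequence_index`).

Spectra live in a simple delimited text format::

    id,label,v1,...,vL[,meta_*]

one spectrum per row, with a fixed length L per file.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Spectrum",
    "SpectralDataset",
    "ImbalanceSpec",
    "MinMaxNormalizer",
    "read_spectra",
    "write_spectra",
    "to_sequence_index",
    "normalize_minmax",
    "resample_length",
    "make_imbalanced_split",
]


@dataclass
class Spectrum:
    """One labeled 1-D measurement sequence.

    Parameters
    ----------
    values
        Ordered real measurements (phase-angle degrees or arbitrary units).
    label
        Class identifier, e.g. ``"solution"`` or ``"gel"``.
    meta
        Optional free-form metadata (experiment id, well id, original
        frequency range in Hz, synthetic/generated flags ...).
    """

    values: np.ndarray
    label: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("spectrum values must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("spectrum values must be finite")

    def __len__(self) -> int:
        return self.values.size


@dataclass
class SpectralDataset:
    """A collection of equal-length labeled spectra.

    ``classes`` is the ordered inventory of distinct labels; the order fixes
    class indices everywhere downstream (one-hot encodings, confusion counts,
    prediction tie-breaks).
    """

    spectra: list[Spectrum]
    classes: list[str] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.spectra:
            raise ValueError("no spectra")
        lengths = {len(s) for s in self.spectra}
        if len(lengths) != 1:
            raise ValueError(f"inconsistent spectrum lengths: {sorted(lengths)}")
        if self.classes is None:
            seen: dict[str, None] = {}
            for s in self.spectra:
                seen.setdefault(s.label, None)
            self.classes = list(seen)
        missing = {s.label for s in self.spectra} - set(self.classes)
        if missing:
            raise ValueError(f"labels not in class inventory: {sorted(missing)}")

    @property
    def length(self) -> int:
        return len(self.spectra[0])

    def __len__(self) -> int:
        return len(self.spectra)

    @property
    def values(self) -> np.ndarray:
        """(n_spectra, length) matrix of measurements, row order preserved."""
        return np.stack([s.values for s in self.spectra])

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.spectra]

    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in self.classes}
        for s in self.spectra:
            counts[s.label] += 1
        return counts

    def subset(self, indices) -> "SpectralDataset":
        return SpectralDataset([self.spectra[i] for i in indices], list(self.classes))

    def by_class(self, label: str) -> "SpectralDataset":
        idx = [i for i, s in enumerate(self.spectra) if s.label == label]
        return self.subset(idx)


@dataclass(frozen=True)
class ImbalanceSpec:
    """Majority/minority identities and per-class training counts.

    The balanced ratio — minority over majority training count — is the
    experimental knob of the case studies (e.g. 150 solution vs 4 gel
    training spectra gives ratio 4/150 ≈ 0.027).
    """

    majority_class: str
    minority_class: str
    majority_n: int
    minority_n: int

    def __post_init__(self) -> None:
        if self.majority_n <= 0 or self.minority_n <= 0:
            raise ValueError("class counts must be positive")
        if self.minority_n > self.majority_n:
            raise ValueError("minority_n must not exceed majority_n")

    @property
    def balanced_ratio(self) -> float:
        """minority_n / majority_n at full precision."""
        return self.minority_n / self.majority_n

    @property
    def ratio_display(self) -> float:
        """Balanced ratio rounded to 3 decimals for reporting."""
        return round(self.balanced_ratio, 3)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def read_spectra(path, delimiter: str = ",") -> SpectralDataset:
    """Read a spectra table (``id,label,v1..vL`` + optional ``meta_*``)."""
    try:
        frame = pd.read_csv(path, sep=delimiter, dtype={"label": str},
                            float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise ValueError("no spectra") from None
    if frame.empty:
        raise ValueError("no spectra")
    required = {"id", "label"}
    if not required.issubset(frame.columns):
        raise ValueError(f"missing required columns {sorted(required - set(frame.columns))}")
    value_cols = [c for c in frame.columns if c.startswith("v") and c[1:].isdigit()]
    value_cols.sort(key=lambda c: int(c[1:]))
    if not value_cols:
        raise ValueError("no value columns v1..vL found")
    meta_cols = [c for c in frame.columns if c.startswith("meta_")]

    spectra = []
    for row_no, (_, row) in enumerate(frame.iterrows(), start=2):  # 1 = header line
        vals = pd.to_numeric(row[value_cols], errors="coerce").to_numpy(dtype=float)
        if np.any(~np.isfinite(vals)):
            bad = value_cols[int(np.flatnonzero(~np.isfinite(vals))[0])]
            raise ValueError(f"non-numeric or non-finite value in row {row_no}, column {bad}")
        meta = {c[len("meta_"):]: row[c] for c in meta_cols if pd.notna(row[c])}
        meta["id"] = row["id"]
        spectra.append(Spectrum(vals, str(row["label"]), meta))
    return SpectralDataset(spectra)


def write_spectra(dataset: SpectralDataset, path, delimiter: str = ",") -> None:
    """Write a dataset in the native delimited format (re-readable losslessly)."""
    meta_keys = sorted({k for s in dataset.spectra for k in s.meta if k != "id"})
    records = []
    for i, s in enumerate(dataset.spectra):
        rec = {"id": s.meta.get("id", i), "label": s.label}
        rec.update({f"v{j + 1}": v for j, v in enumerate(s.values)})
        for k in meta_keys:
            rec[f"meta_{k}"] = s.meta.get(k, "")
        records.append(rec)
    cols = ["id", "label"] + [f"v{j + 1}" for j in range(dataset.length)]
    cols += [f"meta_{k}" for k in meta_keys]
    frame = pd.DataFrame.from_records(records, columns=cols)
    # repr-roundtrip float format keeps write->read->write byte-stable
    frame.to_csv(path, sep=delimiter, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def to_sequence_index(values, frequencies, label: str = "", meta: dict | None = None) -> Spectrum:
    """Discard the frequency axis, keeping the measurement sequence 1..N.

    Different experiments sweep different frequency windows (e.g.
    26,013.75–37,000 Hz vs 31,012.5–41,000 Hz), so the common axis across
    experiments is simply the sensor-measurement index.  Values are
    untouched; the original range is preserved in ``meta``.
    """
    values = np.asarray(values, dtype=float)
    frequencies = np.asarray(frequencies, dtype=float)
    if values.shape != frequencies.shape:
        raise ValueError("values and frequencies must have equal length")
    if frequencies.size > 1 and not np.all(np.diff(frequencies) > 0):
        raise ValueError("frequencies must be strictly increasing")
    meta = dict(meta or {})
    meta["freq_min_hz"] = float(frequencies[0])
    meta["freq_max_hz"] = float(frequencies[-1])
    return Spectrum(values.copy(), label, meta)


@dataclass(frozen=True)
class MinMaxNormalizer:
    """Affine map sending a global [data_min, data_max] onto [lo, hi]."""

    lo: float
    hi: float
    data_min: float
    data_max: float

    @classmethod
    def fit(cls, dataset: SpectralDataset, lo: float = -1.0, hi: float = 1.0) -> "MinMaxNormalizer":
        if not lo < hi:
            raise ValueError("lo must be < hi")
        v = dataset.values
        return cls(float(lo), float(hi), float(v.min()), float(v.max()))

    def transform_values(self, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        span = self.data_max - self.data_min
        if span == 0.0:
            logger.warning("constant dataset: mapping all values to the midpoint")
            return np.full_like(values, 0.5 * (self.lo + self.hi))
        return self.lo + (values - self.data_min) * (self.hi - self.lo) / span

    def invert_values(self, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        span = self.data_max - self.data_min
        if span == 0.0:
            return np.full_like(values, 0.5 * (self.data_min + self.data_max))
        return self.data_min + (values - self.lo) * span / (self.hi - self.lo)

    def transform(self, dataset: SpectralDataset) -> SpectralDataset:
        spectra = [Spectrum(self.transform_values(s.values), s.label, dict(s.meta))
                   for s in dataset.spectra]
        return SpectralDataset(spectra, list(dataset.classes))

    def invert(self, dataset: SpectralDataset) -> SpectralDataset:
        spectra = [Spectrum(self.invert_values(s.values), s.label, dict(s.meta))
                   for s in dataset.spectra]
        return SpectralDataset(spectra, list(dataset.classes))


def normalize_minmax(dataset: SpectralDataset, lo: float = -1.0, hi: float = 1.0,
                     norm: MinMaxNormalizer | None = None):
    """Scale a dataset into [lo, hi]; returns (scaled dataset, normalizer).

    Fit the constants on the training split only and pass the returned
    normalizer back in for test data, so no test information leaks into the
    scaling.  [-1, 1] is the natural target because the generator ends in a
    bounded symmetric (tanh) activation.
    """
    if norm is None:
        norm = MinMaxNormalizer.fit(dataset, lo, hi)
    return norm.transform(dataset), norm


def resample_length(spectrum: Spectrum, target_length: int) -> Spectrum:
    """Linear interpolation onto ``target_length`` equally spaced points."""
    if target_length < 2:
        raise ValueError("target_length must be >= 2")
    n = len(spectrum)
    if target_length == n:
        return replace(spectrum, values=spectrum.values.copy(), meta=dict(spectrum.meta))
    x_old = np.linspace(0.0, 1.0, n)
    x_new = np.linspace(0.0, 1.0, target_length)
    return Spectrum(np.interp(x_new, x_old, spectrum.values), spectrum.label,
                    dict(spectrum.meta))


def make_imbalanced_split(dataset: SpectralDataset, spec: ImbalanceSpec, seed: int):
    """Stratified random split realizing an imbalanced training design.

    Draws exactly ``majority_n`` + ``minority_n`` training spectra without
    replacement (simple random sampling per class, seed-controlled); every
    remaining spectrum goes to the test set.

    Returns
    -------
    (train, test, realized) where ``realized`` is the spec with the achieved
    counts (identical to ``spec`` when the preconditions hold).
    """
    counts = dataset.class_counts()
    for cls, need in ((spec.majority_class, spec.majority_n),
                      (spec.minority_class, spec.minority_n)):
        have = counts.get(cls, 0)
        if have < need:
            raise ValueError(f"class {cls!r} has only {have} spectra, {need} requested")

    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    for cls, need in ((spec.majority_class, spec.majority_n),
                      (spec.minority_class, spec.minority_n)):
        pool = np.array([i for i, s in enumerate(dataset.spectra) if s.label == cls])
        train_idx.extend(rng.choice(pool, size=need, replace=False).tolist())
    train_set = set(train_idx)
    test_idx = [i for i in range(len(dataset)) if i not in train_set]
    train = dataset.subset(sorted(train_idx))
    test = dataset.subset(test_idx)
    return train, test, spec


def most_square_grid(length: int) -> tuple[int, int]:
    """Factor L as rows x cols with rows <= cols and rows maximal (800 -> 25x32)."""
    rows = 1
    for r in range(1, int(math.isqrt(length)) + 1):
        if length % r == 0:
            rows = r
    return rows, length // rows
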