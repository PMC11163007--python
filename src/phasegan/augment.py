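"""Sampling-based augmentation baselines and the uniform augmenter registry.

SMOTE creates synthetic minority spectra by linear interpolation between a
minority sample and one of its k nearest minority neighbors.
Borderline-SMOTE (variant 1) restricts the interpolation parents to the
DANGER set: minority samples whose m-neighborhood among *all* training
samples is majority-dominated (at least half but not all neighbors from
other classes).  Both operate on the spectrum value vectors with Euclidean
distance, which is why training data should be min-max normalized first.

Every augmentation method — including the three-player GAN — plugs into the
same registry keyed by name, so the evaluation protocol treats them
uniformly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .spectra import SpectralDataset, Spectrum

logger = logging.getLogger(__name__)

__all__ = ["AugmenterSpec", "smote_oversample", "borderline_smote_oversample",
           "augment_to_balance", "register_augmenter", "available_augmenters"]


@dataclass
class AugmenterSpec:
    """Configuration shared by the sampling augmenters.

    ``k_neighbors`` lies in the tuning range [1, 5]; ``target_counts`` maps
    each label to its desired post-augmentation count (never below the
    current count — augmentation is additive).
    """

    name: str = "smote"
    k_neighbors: int = 5
    target_counts: dict[str, int] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.k_neighbors <= 5:
            raise ValueError("k_neighbors must lie in [1, 5]")


def _validate_targets(train: SpectralDataset, spec: AugmenterSpec) -> dict[str, int]:
    counts = train.class_counts()
    targets = {}
    for cls, target in spec.target_counts.items():
        if cls not in counts:
            raise ValueError(f"unknown class {cls!r} in target_counts")
        if target < counts[cls]:
            raise ValueError(f"target for {cls!r} below current count")
        targets[cls] = target
    return targets


def _interpolate(train: SpectralDataset, cls: str, parents: np.ndarray,
                 parent_ids: list[int], X_min: np.ndarray, neighbor_idx: np.ndarray,
                 n_needed: int, rng: np.random.Generator) -> list[Spectrum]:
    """Round-robin SMOTE interpolation from given parent rows.

    ``neighbor_idx[i]`` holds the minority-set indices of parent i's k
    nearest minority neighbors (self excluded).
    """
    out = []
    for j in range(n_needed):
        p = j % len(parents)
        nn = int(rng.choice(neighbor_idx[p]))
        u = float(rng.uniform())
        synth = parents[p] + u * (X_min[nn] - parents[p])
        out.append(Spectrum(synth, cls, {"synthetic_smote": True,
                                         "parent_id": parent_ids[p], "u": u}))
    return out


def smote_oversample(train: SpectralDataset, spec: AugmenterSpec) -> SpectralDataset:
    """SMOTE: interpolate between minority samples and minority neighbors.

    For each synthetic sample the parent is chosen round-robin over the
    minority class (guaranteeing coverage), a neighbor uniformly among the
    parent's ``k_neighbors`` nearest minority samples, and the interpolation
    weight u ~ Uniform(0, 1).  Originals are preserved unmodified.
    """
    targets = _validate_targets(train, spec)
    counts = train.class_counts()
    rng = np.random.default_rng(spec.seed)
    new_spectra = list(train.spectra)
    for cls in train.classes:
        need = targets.get(cls, counts[cls]) - counts[cls]
        if need == 0:
            continue
        members = [i for i, s in enumerate(train.spectra) if s.label == cls]
        if len(members) < 2:
            raise ValueError(f"cannot interpolate: class {cls!r} has fewer than 2 samples")
        if spec.k_neighbors >= len(members):
            raise ValueError(f"k_neighbors={spec.k_neighbors} must be < class size "
                             f"{len(members)} for {cls!r}")
        X = np.stack([train.spectra[i].values for i in members])
        nn = NearestNeighbors(n_neighbors=spec.k_neighbors + 1).fit(X)
        neighbor_idx = nn.kneighbors(X, return_distance=False)[:, 1:]  # drop self
        new_spectra.extend(_interpolate(train, cls, X, members, X, neighbor_idx,
                                        need, rng))
    return SpectralDataset(new_spectra, list(train.classes))


def danger_set(train: SpectralDataset, cls: str, m_neighbors: int) -> list[int]:
    """Indices (into ``train``) of class ``cls`` samples on the borderline.

    A minority sample is DANGER if, among its ``m_neighbors`` nearest
    neighbors over the whole training set (self excluded), the number from
    other classes is at least m/2 but strictly less than m.  Samples with
    all-majority neighborhoods are noise; those with a minority-dominated
    neighborhood are safe; neither is used as a parent.
    """
    labels = np.array(train.labels)
    X = train.values
    if m_neighbors >= len(train):
        raise ValueError("m_neighbors must be < training set size")
    nn = NearestNeighbors(n_neighbors=m_neighbors + 1).fit(X)
    neighbor_idx = nn.kneighbors(X, return_distance=False)[:, 1:]
    danger = []
    for i in np.flatnonzero(labels == cls):
        n_majority = int(np.sum(labels[neighbor_idx[i]] != cls))
        if m_neighbors / 2.0 <= n_majority < m_neighbors:
            danger.append(int(i))
    return danger


def borderline_smote_oversample(train: SpectralDataset, spec: AugmenterSpec) -> SpectralDataset:
    """Borderline-SMOTE (variant 1): interpolate only from DANGER parents.

    Neighborhood membership is judged against all classes; interpolation
    partners are still drawn from the minority class.  If no sample is in
    DANGER the method degrades to plain SMOTE with a warning.
    """
    targets = _validate_targets(train, spec)
    counts = train.class_counts()
    rng = np.random.default_rng(spec.seed)
    new_spectra = list(train.spectra)
    for cls in train.classes:
        need = targets.get(cls, counts[cls]) - counts[cls]
        if need == 0:
            continue
        members = [i for i, s in enumerate(train.spectra) if s.label == cls]
        if len(members) < 2:
            raise ValueError(f"cannot interpolate: class {cls!r} has fewer than 2 samples")
        if spec.k_neighbors >= len(members):
            raise ValueError(f"k_neighbors={spec.k_neighbors} must be < class size "
                             f"{len(members)} for {cls!r}")
        others = [i for i, s in enumerate(train.spectra) if s.label != cls]
        if not others:
            raise ValueError("borderline-SMOTE requires a non-empty majority class")
        danger = danger_set(train, cls, spec.k_neighbors)
        if not danger:
            logger.warning("empty DANGER set for class %r; falling back to SMOTE", cls)
            danger = members
        X_min = np.stack([train.spectra[i].values for i in members])
        nn = NearestNeighbors(n_neighbors=spec.k_neighbors + 1).fit(X_min)
        pos_in_min = {g: j for j, g in enumerate(members)}
        parents = np.stack([train.spectra[i].values for i in danger])
        neighbor_idx = nn.kneighbors(parents, return_distance=False)
        # drop the parent itself if present, keep k columns
        cleaned = []
        for row_i, g in enumerate(danger):
            row = [j for j in neighbor_idx[row_i] if j != pos_in_min[g]]
            cleaned.append(row[: spec.k_neighbors])
        new_spectra.extend(_interpolate(train, cls, parents, danger, X_min,
                                        np.array(cleaned), need, rng))
    return SpectralDataset(new_spectra, list(train.classes))


# ---------------------------------------------------------------------------
# Registry
# ---------------------------------------------------------------------------

def _none_augmenter(train: SpectralDataset, spec: AugmenterSpec) -> SpectralDataset:
    return train


_REGISTRY = {
    "none": _none_augmenter,
    "smote": smote_oversample,
    "b-smote": borderline_smote_oversample,
}


def register_augmenter(name: str, fn) -> None:
    """Register an augmenter callable ``fn(train, spec) -> SpectralDataset``."""
    _REGISTRY[name] = fn


def available_augmenters() -> list[str]:
    return sorted(_REGISTRY)


def augment_to_balance(train: SpectralDataset, augmenter: str, seed: int,
                       k_neighbors: int = 5) -> SpectralDataset:
    """Bring every class up to the majority count using the named augmenter."""
    if len(train.classes) < 2:
        raise ValueError("need at least 2 classes to balance")
    if augmenter not in _REGISTRY:
        raise ValueError(f"unknown augmenter {augmenter!r}; "
                         f"available: {available_augmenters()}")
    counts = train.class_counts()
    majority = max(counts.values())
    if all(c == majority for c in counts.values()):
        return train
    spec = AugmenterSpec(name=augmenter, k_neighbors=k_neighbors,
                         target_counts={c: majority for c in counts}, seed=seed)
    out = _REGISTRY[augmenter](train, spec)
    return out
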