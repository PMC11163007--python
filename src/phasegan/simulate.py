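"""Synthetic hydrogel phase-angle spectra.

Real impedance phase spectra from cantilever sensors show a single
resonance-like dip whose position, width and depth shift with the material
phase (solution vs gel).  The simulator emulates exactly that structure:

* a per-class mean curve = linear baseline + Gaussian peak,
* per-spectrum jitter of the peak position (experiment-to-experiment and
  well-to-well variation),
* additive white Gaussian measurement noise,
* a ``similarity`` knob in [0, 1] that blends every class mean toward the
  across-class average curve — at 1 the classes are indistinguishable.  This
  reproduces the spectrum of difficulty between the well-separated
  thermogelling case and the supramolecular case whose solution and gel
  spectra are nearly identical.

A plate-scan generator sweeps composition across wells of a 96-well plate
and returns the ground-truth sol-gel transition index, which the labeling
procedures must recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .spectra import SpectralDataset, Spectrum

__all__ = ["ClassModel", "SimConfig", "class_mean_curve", "simulate_dataset",
           "simulate_platescan", "default_class_models"]


@dataclass(frozen=True)
class ClassModel:
    """Parameters of one class's mean curve on the unit index axis t in [0,1].

    curve(t) = baseline_offset + baseline_slope*t
               + peak_depth * exp(-(t - peak_center)^2 / (2 peak_width^2))

    ``peak_depth`` is signed: negative for the downward phase-angle dip.
    """

    peak_center: float
    peak_width: float
    peak_depth: float
    baseline_slope: float = 0.0
    baseline_offset: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.peak_center <= 1.0:
            raise ValueError("peak_center must lie in [0, 1]")
        if self.peak_width <= 0:
            raise ValueError("peak_width must be positive")


def default_class_models() -> dict[str, ClassModel]:
    """Two-phase models loosely emulating thermogelling phase-angle spectra.

    Gelation shifts the resonance dip to higher index, broadens it and damps
    its depth; values are in phase-angle degrees.
    """
    return {
        "solution": ClassModel(peak_center=0.42, peak_width=0.07, peak_depth=-30.0,
                               baseline_slope=-4.0, baseline_offset=-18.0),
        "gel": ClassModel(peak_center=0.58, peak_width=0.12, peak_depth=-18.0,
                          baseline_slope=-4.0, baseline_offset=-20.0),
    }


@dataclass
class SimConfig:
    """Study conditions for one simulated dataset.

    Defaults: length 200 (desk-scale stand-in for the 800-point sensor
    sweep), noise_sd 1.5 degrees, peak-center jitter sd 0.03 of the axis,
    similarity 0 (classes as configured).
    """

    length: int = 200
    class_models: dict[str, ClassModel] = field(default_factory=default_class_models)
    n_per_class: dict[str, int] = field(default_factory=lambda: {"solution": 181, "gel": 107})
    noise_sd: float = 1.5
    similarity: float = 0.0
    jitter_sd: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length < 2:
            raise ValueError("length must be >= 2")
        if len(self.class_models) < 2:
            raise ValueError("need at least 2 classes")
        if set(self.n_per_class) - set(self.class_models):
            raise ValueError("n_per_class contains unknown classes")
        if any(n < 1 for n in self.n_per_class.values()):
            raise ValueError("all class counts must be >= 1")
        if not 0.0 <= self.similarity <= 1.0:
            raise ValueError("similarity must lie in [0, 1]")
        if self.noise_sd < 0 or self.jitter_sd < 0:
            raise ValueError("noise_sd and jitter_sd must be nonnegative")


def class_mean_curve(model: ClassModel, length: int) -> np.ndarray:
    """Evaluate a class mean curve at t = i/(length-1), i = 0..length-1."""
    if length < 2:
        raise ValueError("length must be >= 2")
    t = np.linspace(0.0, 1.0, length)
    peak = model.peak_depth * np.exp(-((t - model.peak_center) ** 2)
                                     / (2.0 * model.peak_width ** 2))
    return model.baseline_offset + model.baseline_slope * t + peak


def _average_curve(models: dict[str, ClassModel], length: int) -> np.ndarray:
    return np.mean([class_mean_curve(m, length) for m in models.values()], axis=0)


def simulate_dataset(config: SimConfig) -> SpectralDataset:
    """Draw a labeled dataset under the configured study conditions.

    Per spectrum: jitter the class's peak center, evaluate its curve, blend
    it ``similarity`` of the way toward the across-class average curve, add
    white Gaussian noise.  Fully deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    s = config.similarity
    models = config.class_models

    def blended_curve(label: str, delta: float) -> np.ndarray:
        """Blend of jitter-shifted class curves: the per-spectrum jitter
        shifts every constituent peak by the same delta, so within-class
        variation keeps its full strength even when the class means are
        blended to near-identity."""
        shifted = {
            k: class_mean_curve(
                replace(m, peak_center=float(np.clip(m.peak_center + delta, 0, 1))),
                config.length)
            for k, m in models.items()
        }
        avg = np.mean(list(shifted.values()), axis=0)
        return (1.0 - s) * shifted[label] + s * avg

    spectra: list[Spectrum] = []
    for label in models:
        n = config.n_per_class.get(label, 0)
        for i in range(n):
            delta = rng.normal(0.0, config.jitter_sd)
            values = blended_curve(label, delta)
            values = values + rng.normal(0.0, config.noise_sd, size=config.length)
            spectra.append(Spectrum(values, label, {"class_index": i, "synthetic": True}))
    return SpectralDataset(spectra, list(config.class_models))


def blended_class_mean(config: SimConfig, label: str) -> np.ndarray:
    """The noise-free, jitter-free mean curve of a class after blending."""
    avg = _average_curve(config.class_models, config.length)
    curve = class_mean_curve(config.class_models[label], config.length)
    return (1.0 - config.similarity) * curve + config.similarity * avg


def simulate_platescan(n_wells: int, transition_frac: float, config: SimConfig,
                       sharpness: float = 1.5):
    """Simulate a concentration sweep across a well plate.

    Wells are ordered by composition.  Wells with index below
    ``floor(transition_frac * n_wells)`` belong to the first configured class
    ("before" the sol-gel transition), the rest to the second.  Spectra morph
    smoothly between the two class curves with a logistic weight centred at
    the transition (width ``sharpness`` wells), so any scalar summary of the
    spectrum — e.g. its value at the peak position — varies sigmoidally
    across the plate, as in a real gelation sweep.

    Returns ``(dataset, true_transition_index)`` where the index is the
    first well of the second class.
    """
    if n_wells < 4:
        raise ValueError("n_wells must be >= 4")
    if not 0.0 < transition_frac < 1.0:
        raise ValueError("transition_frac must lie in (0, 1)")
    labels = list(config.class_models)
    if len(labels) != 2:
        raise ValueError("platescan simulation requires exactly 2 classes")
    label_a, label_b = labels
    k = int(np.floor(transition_frac * n_wells))

    rng = np.random.default_rng(config.seed)
    curve_a = blended_class_mean(config, label_a)
    curve_b = blended_class_mean(config, label_b)
    spectra = []
    wells = np.arange(n_wells)
    # logistic weight centred between wells k-1 and k
    w = 1.0 / (1.0 + np.exp(-(wells - (k - 0.5)) / sharpness))
    for i in range(n_wells):
        values = (1.0 - w[i]) * curve_a + w[i] * curve_b
        values = values + rng.normal(0.0, config.noise_sd, size=config.length)
        label = label_a if i < k else label_b
        spectra.append(Spectrum(values, label, {"well": i, "synthetic": True}))
    return SpectralDataset(spectra, labels), k
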