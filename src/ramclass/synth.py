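"""Synthetic liquid-sample Raman spectra with known ground truth.

Each specimen gets a random low-order polynomial baseline (emulating the
broad fluorescence background of biological fluids) and specimen-level
perturbations of a shared set of peak amplitudes; each replicate scan adds
iid Gaussian detector noise. Class membership acts multiplicatively on the
peak amplitudes (with an optional peak-shift effect for harder problems), so
the class signal lives in relative band intensities — the structure the
preprocessing and classification chain assumes. Peaks are Gaussian by
default, with a Lorentzian option.

The generator is deterministic for a fixed seed and records every baseline
coefficient and effective amplitude, so baseline-recovery and
parameter-recovery tests have exact ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .io import SpectralDataset, write_dataset

#: default Raman bands (cm^-1) loosely placed on common urine/biofluid features
DEFAULT_PEAK_CENTERS = (640.0, 1003.0, 1248.0, 1445.0, 1660.0)
DEFAULT_PEAK_WIDTHS = (12.0, 9.0, 16.0, 14.0, 11.0)
DEFAULT_BASE_AMPLITUDES = (0.6, 1.0, 0.5, 0.8, 0.7)

#: relative band-intensity pattern of a class effect. A scalar factor on all
#: peaks would be cancelled by vector normalization; disease-like signal must
#: change band ratios, so the default effect scales peaks in opposite
#: directions (cycled if there are more peaks).
EFFECT_PATTERN = (1.0, -0.6, 0.7, 0.0, -0.7)


def class_effect_vector(strength: float, n_peaks: int) -> np.ndarray:
    """Per-peak amplitude factors for a class with the given contrast strength.

    ``strength`` is the maximal relative band change: 0 gives all-ones (no
    class signal), 0.35 gives factors between 0.65 and 1.35.
    """
    pattern = np.resize(np.asarray(EFFECT_PATTERN), n_peaks)
    return 1.0 + strength * pattern


@dataclass
class SynthConfig:
    """Parameters of the synthetic spectrum generator.

    The defaults mirror the acquisition conditions the pipeline targets: a
    400-1800 cm^-1 grid at 1 cm^-1 spacing, two classes, 10 replicate scans
    per specimen, smooth cubic baselines large relative to the peaks, mild
    specimen-to-specimen amplitude variability and small replicate noise.

    class_effects maps each class label to multiplicative peak-amplitude
    factors (scalar, or one per peak). The default gives class i the
    band-ratio pattern ``class_effect_vector(0.35 * i, n_peaks)``; note a
    scalar factor is removed by vector normalization downstream, so class
    signal that should survive preprocessing must alter band ratios.
    class_shifts optionally
    shifts that class's peak centers (cm^-1). specimen_sd is the log-normal
    sigma of per-specimen, per-peak amplitude factors; fingerprint_sd adds a
    smooth specimen-specific spectral component (correlation length
    ``fingerprint_corr`` cm^-1, per-point standard deviation in detector
    units) emulating the broadband compositional variability of biological
    fluids — it spreads within-class variance over many principal
    components, which is what lets high-PC-count models over-fit; noise_sd
    is the additive per-point replicate noise standard deviation.
    """

    grid_low: float = 400.0
    grid_high: float = 1800.0
    grid_step: float = 1.0
    n_specimens_per_class: int | Sequence[int] = 20
    n_replicates: int = 10
    classes: Sequence[str] = ("healthy", "unhealthy")
    peak_centers: Sequence[float] = DEFAULT_PEAK_CENTERS
    peak_widths: Sequence[float] = DEFAULT_PEAK_WIDTHS
    base_amplitudes: Sequence[float] = DEFAULT_BASE_AMPLITUDES
    class_effects: Mapping[str, float | Sequence[float]] | None = None
    class_shifts: Mapping[str, float] | None = None
    baseline_coeff_ranges: Sequence[tuple[float, float]] = (
        (20.0, 60.0),
        (-10.0, 10.0),
        (-8.0, 8.0),
        (-4.0, 4.0),
    )
    specimen_sd: float = 0.08
    fingerprint_sd: float = 0.01
    fingerprint_corr: float = 30.0
    noise_sd: float = 0.02
    lorentzian: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_low >= self.grid_high or self.grid_step <= 0:
            raise ValueError("need grid_low < grid_high and grid_step > 0")
        if len(self.peak_centers) != len(self.peak_widths) or len(self.peak_centers) != len(
            self.base_amplitudes
        ):
            raise ValueError("peak_centers, peak_widths, base_amplitudes must have equal length")
        if any(w <= 0 for w in self.peak_widths):
            raise ValueError("peak widths must be > 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.noise_sd < 0 or self.specimen_sd < 0 or self.fingerprint_sd < 0:
            raise ValueError("noise_sd, specimen_sd and fingerprint_sd must be >= 0")
        if self.fingerprint_corr <= 0:
            raise ValueError("fingerprint_corr must be > 0")
        if len(self.classes) < 1:
            raise ValueError("need at least one class")
        if len(self.baseline_coeff_ranges) > 4:
            raise ValueError("baseline order is limited to cubic (4 coefficients)")
        if self.class_effects is None:
            # band-ratio contrast growing with class index; the first class
            # is the reference (all factors 1)
            n_peaks = len(self.peak_centers)
            self.class_effects = {
                c: class_effect_vector(0.35 * i, n_peaks) for i, c in enumerate(self.classes)
            }

    def specimens_per_class(self) -> list[int]:
        if isinstance(self.n_specimens_per_class, int):
            return [self.n_specimens_per_class] * len(self.classes)
        counts = list(self.n_specimens_per_class)
        if len(counts) != len(self.classes):
            raise ValueError("n_specimens_per_class sequence must match the class list")
        return counts

    def grid(self) -> np.ndarray:
        n = int(round((self.grid_high - self.grid_low) / self.grid_step)) + 1
        return self.grid_low + self.grid_step * np.arange(n)


@dataclass
class GroundTruth:
    """Generative record: per-specimen baseline coefficients and amplitudes."""

    grid: np.ndarray
    grid_low: float
    grid_high: float
    baseline_coeffs: dict[str, np.ndarray]  # coefficients in the scaled coordinate
    peak_amplitudes: dict[str, np.ndarray]  # effective per-peak amplitude
    peak_centers: dict[str, np.ndarray]
    peak_widths: np.ndarray
    class_of: dict[str, str]

    def table(self) -> pd.DataFrame:
        rows = []
        for sid, coeffs in self.baseline_coeffs.items():
            row = {"specimen_id": sid, "class_label": self.class_of[sid]}
            row.update({f"baseline_c{i}": c for i, c in enumerate(coeffs)})
            row.update({f"amplitude_{i}": a for i, a in enumerate(self.peak_amplitudes[sid])})
            rows.append(row)
        return pd.DataFrame(rows)


def _peak_profile(grid, center, width, lorentzian):
    if lorentzian:
        return 1.0 / (1.0 + ((grid - center) / width) ** 2)
    return np.exp(-0.5 * ((grid - center) / width) ** 2)


def _eval_baseline(grid, low, high, coeffs):
    t = (grid - low) / (high - low)
    return np.polynomial.polynomial.polyval(t, coeffs)


def generate_dataset(cfg: SynthConfig):
    """Draw a synthetic SpectralDataset and its generative ground truth.

    Bit-identical for a fixed config (including the seed).
    """
    rng = np.random.default_rng(cfg.seed)
    grid = cfg.grid()
    lo, hi = (np.asarray(b, dtype=float) for b in zip(*cfg.baseline_coeff_ranges))
    widths = np.asarray(cfg.peak_widths, dtype=float)
    base_amp = np.asarray(cfg.base_amplitudes, dtype=float)

    rows, meta_rows = [], []
    bl_coeffs, amps, centers_rec, class_of = {}, {}, {}, {}
    for c, n_spec in zip(cfg.classes, cfg.specimens_per_class()):
        effect = np.broadcast_to(
            np.asarray(cfg.class_effects[c], dtype=float), base_amp.shape
        ).copy()
        shift = float((cfg.class_shifts or {}).get(c, 0.0))
        centers = np.asarray(cfg.peak_centers, dtype=float) + shift
        for i in range(n_spec):
            sid = f"{c}_{i:03d}"
            coeffs = rng.uniform(lo, hi)
            spec_factor = np.exp(rng.normal(0.0, cfg.specimen_sd, size=len(base_amp)))
            amplitude = base_amp * effect * spec_factor
            baseline = _eval_baseline(grid, cfg.grid_low, cfg.grid_high, coeffs)
            signal = baseline + sum(
                a * _peak_profile(grid, mu, w, cfg.lorentzian)
                for a, mu, w in zip(amplitude, centers, widths)
            )
            if cfg.fingerprint_sd > 0:
                v = gaussian_filter1d(
                    rng.normal(size=len(grid)), cfg.fingerprint_corr / cfg.grid_step
                )
                sd = v.std()
                if sd > 0:
                    signal = signal + cfg.fingerprint_sd * v / sd
            for rep in range(cfg.n_replicates):
                noise = rng.normal(0.0, cfg.noise_sd, size=len(grid)) if cfg.noise_sd else 0.0
                rows.append(signal + noise)
                meta_rows.append(
                    {
                        "scan_id": f"{sid}_r{rep + 1:02d}",
                        "specimen_id": sid,
                        "individual_id": sid,
                        "class_label": c,
                        "replicate_index": rep + 1,
                    }
                )
            bl_coeffs[sid] = coeffs
            amps[sid] = amplitude
            centers_rec[sid] = centers
            class_of[sid] = c
    dataset = SpectralDataset(grid, np.vstack(rows), pd.DataFrame(meta_rows))
    truth = GroundTruth(
        grid=grid,
        grid_low=cfg.grid_low,
        grid_high=cfg.grid_high,
        baseline_coeffs=bl_coeffs,
        peak_amplitudes=amps,
        peak_centers=centers_rec,
        peak_widths=widths,
        class_of=class_of,
    )
    return dataset, truth


def ground_truth_baseline(record: GroundTruth, specimen_id: str) -> np.ndarray:
    """Exact generative baseline of one specimen, evaluated on the grid."""
    if specimen_id not in record.baseline_coeffs:
        raise KeyError(f"unknown specimen {specimen_id!r}")
    return _eval_baseline(
        record.grid, record.grid_low, record.grid_high, record.baseline_coeffs[specimen_id]
    )


def write_fixture(cfg: SynthConfig, spectra_path, meta_path, truth_path=None):
    """Generate a dataset and write the CSV pair (+ optional ground-truth sidecar)."""
    dataset, truth = generate_dataset(cfg)
    write_dataset(dataset, spectra_path, meta_path)
    if truth_path is not None:
        truth.table().to_csv(truth_path, index=False)
    return dataset, truth
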