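"""Core data containers shared across the pipeline.

All time series are stored as ``channels x samples`` float arrays; all
connectivity matrices are square, symmetric, with unit diagonal.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

#: Recognised contrast labels, in the order raw optics -> hemoglobin -> fMRI.
CONTRASTS = ("intensity_760", "intensity_850", "HbO", "HbR", "HbT", "BOLD")

MODALITIES = ("fnirs_raw", "fnirs_hb", "fmri_roi")


class NeuroprintError(Exception):
    """Base class for every error raised by this package."""


class InvalidArgumentError(NeuroprintError, ValueError):
    pass


class InvalidDataError(NeuroprintError, ValueError):
    pass


@dataclass
class TimeSeriesRun:
    """One run of multichannel hemodynamic (or raw optical) data.

    Parameters
    ----------
    subject_id, run_id : str
        Labels identifying the recording.
    contrast : str
        One of :data:`CONTRASTS`.
    data : ndarray, shape (n_channels, n_samples)
        Concentrations in uM for hemoglobin contrasts, arbitrary units
        otherwise.
    sampling_rate : float
        Samples per second; must be positive.
    channel_ids : sequence of str
        One label per row of ``data``.
    quality_flags : ndarray of bool, optional
        Per-channel good/bad flags (True = good). Defaults to all-good.
    """

    subject_id: str
    run_id: str
    contrast: str
    data: np.ndarray
    sampling_rate: float
    channel_ids: Sequence[str]
    quality_flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise InvalidArgumentError("data must be 2-D (channels x samples)")
        if self.contrast not in CONTRASTS:
            raise InvalidArgumentError(f"unknown contrast {self.contrast!r}")
        if not self.sampling_rate > 0:
            raise InvalidArgumentError("sampling_rate must be positive")
        self.channel_ids = list(self.channel_ids)
        if len(self.channel_ids) != self.data.shape[0]:
            raise InvalidArgumentError(
                f"{len(self.channel_ids)} channel ids for "
                f"{self.data.shape[0]} data rows"
            )
        if self.quality_flags is None:
            self.quality_flags = np.ones(self.data.shape[0], dtype=bool)
        else:
            self.quality_flags = np.asarray(self.quality_flags, dtype=bool)
            if self.quality_flags.shape != (self.data.shape[0],):
                raise InvalidArgumentError("quality_flags length mismatch")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def copy_with(self, **kwargs) -> "TimeSeriesRun":
        """Shallow copy with selected fields replaced (data is copied)."""
        if "data" not in kwargs:
            kwargs["data"] = self.data.copy()
        return replace(self, **kwargs)

    def select_channels(self, index: Sequence[int]) -> "TimeSeriesRun":
        index = np.asarray(index, dtype=int)
        return replace(
            self,
            data=self.data[index].copy(),
            channel_ids=[self.channel_ids[i] for i in index],
            quality_flags=self.quality_flags[index].copy(),
        )


@dataclass
class SubjectSignature:
    """Ground-truth latent correlation structure of one synthetic subject."""

    subject_id: str
    target_correlation: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.target_correlation, dtype=float)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise InvalidArgumentError("target_correlation must be square")
        if not np.allclose(c, c.T, atol=1e-10):
            raise InvalidArgumentError("target_correlation must be symmetric")
        if not np.allclose(np.diag(c), 1.0, atol=1e-10):
            raise InvalidArgumentError("target_correlation diagonal must be 1")
        if np.linalg.eigvalsh(c)[0] <= 0:
            raise InvalidArgumentError("target_correlation must be SPD")
        self.target_correlation = c

    @property
    def n_channels(self) -> int:
        return self.target_correlation.shape[0]


@dataclass
class CohortConfig:
    """Parameters for synthetic cohort generation.

    ``signature_strength`` and ``global_amplitude`` are variance shares of
    the subject-specific latent structure and the shared global series; the
    remainder is channel-independent AR noise.
    """

    n_subjects: int = 21
    n_runs: int = 5
    duration: float = 360.0
    sampling_rate: float = 7.8
    n_channels: int = 48
    modality: str = "fmri_roi"
    signature_strength: float = 0.6
    global_amplitude: float = 0.1
    ar_coefficients: tuple[float, ...] = (0.5, 0.2)
    spike_rate: float = 0.0
    shift_rate: float = 0.0
    run_jitter_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise InvalidArgumentError("n_subjects must be >= 2")
        if self.n_runs < 2:
            raise InvalidArgumentError("n_runs must be >= 2")
        if not self.sampling_rate > 0:
            raise InvalidArgumentError("sampling_rate must be positive")
        if self.modality not in MODALITIES:
            raise InvalidArgumentError(f"unknown modality {self.modality!r}")
        if not 0.0 <= self.signature_strength <= 1.0:
            raise InvalidArgumentError("signature_strength must be in [0,1]")
        if not 0.0 <= self.global_amplitude <= 1.0:
            raise InvalidArgumentError("global_amplitude must be in [0,1]")
        if self.signature_strength + self.global_amplitude > 1.0 + 1e-12:
            raise InvalidArgumentError(
                "signature_strength + global_amplitude must be <= 1"
            )

    @property
    def n_samples(self) -> int:
        return int(np.floor(self.duration * self.sampling_rate))


@dataclass
class CohortDataset:
    """Subjects -> runs -> contrasts; the unit consumed by experiments."""

    runs: list[TimeSeriesRun] = field(default_factory=list)
    signatures: dict[str, SubjectSignature] = field(default_factory=dict)

    def subjects(self) -> list[str]:
        return sorted({r.subject_id for r in self.runs})

    def run_ids(self, subject_id: str) -> list[str]:
        return sorted({r.run_id for r in self.runs if r.subject_id == subject_id})

    def runs_for(
        self, subject_id: str, contrast: str | None = None
    ) -> list[TimeSeriesRun]:
        out = [r for r in self.runs if r.subject_id == subject_id]
        if contrast is not None:
            out = [r for r in out if r.contrast == contrast]
        return sorted(out, key=lambda r: r.run_id)

    def run_group(self, subject_id: str, run_id: str) -> list[TimeSeriesRun]:
        return [
            r for r in self.runs
            if r.subject_id == subject_id and r.run_id == run_id
        ]

    def contrasts(self) -> list[str]:
        return sorted({r.contrast for r in self.runs}, key=CONTRASTS.index)

    def __len__(self) -> int:
        return len(self.runs)


@dataclass
class FCMatrix:
    """Symmetric correlation matrix over channels/ROIs with unit diagonal."""

    values: np.ndarray
    labels: Sequence[str]
    subject_id: str = ""
    run_id: str = ""
    contrast: str = "BOLD"
    flagged_channels: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise InvalidArgumentError("FC values must be square")
        if not np.allclose(v, v.T, atol=1e-8):
            raise InvalidArgumentError("FC values must be symmetric")
        v = 0.5 * (v + v.T)
        if not np.allclose(np.diag(v), 1.0, atol=1e-8):
            raise InvalidArgumentError("FC diagonal must be 1")
        if np.max(np.abs(v)) > 1.0 + 1e-8:
            raise InvalidArgumentError("FC entries must lie in [-1, 1]")
        np.fill_diagonal(v, 1.0)
        self.values = np.clip(v, -1.0, 1.0)
        self.labels = list(self.labels)
        if len(self.labels) != v.shape[0]:
            raise InvalidArgumentError("label count mismatch")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def select(self, index: Sequence[int]) -> "FCMatrix":
        index = np.asarray(index, dtype=int)
        return FCMatrix(
            values=self.values[np.ix_(index, index)].copy(),
            labels=[self.labels[i] for i in index],
            subject_id=self.subject_id,
            run_id=self.run_id,
            contrast=self.contrast,
        )


@dataclass
class IdentificationResult:
    """Outcome of one repeated leave-one-out identification experiment."""

    method: str
    accuracies: np.ndarray                  # percentage per repetition
    predictions: np.ndarray                 # (n_reps, n_subjects) indices
    subjects: Sequence[str]                 # index -> subject id
    tie_count: int
    n_repetitions: int
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.accuracies = np.asarray(self.accuracies, dtype=float)
        if self.accuracies.shape != (self.n_repetitions,):
            raise InvalidArgumentError("one accuracy per repetition required")
        if np.any(self.accuracies < 0) or np.any(self.accuracies > 100):
            raise InvalidArgumentError("accuracies must lie in [0, 100]")

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def sd_accuracy(self) -> float:
        return float(np.std(self.accuracies, ddof=1))


@dataclass
class AccuracyModelFit:
    """Fitted accuracy-saturation curve ``alpha * (1 - exp(-gamma * n))``."""

    alpha: float
    gamma: float
    chi2: float
    dof: int
    critical_at_0p01: float | None = None
    ar_thresholds: dict[float, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 100:
            raise InvalidArgumentError("alpha must lie in (0, 100]")
        if not self.gamma > 0:
            raise InvalidArgumentError("gamma must be positive")
        if self.chi2 < 0:
            raise InvalidArgumentError("chi2 must be >= 0")

    def predict(self, n_rois: np.ndarray | float) -> np.ndarray | float:
        return self.alpha * (1.0 - np.exp(-self.gamma * np.asarray(n_rois, dtype=float)))
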