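"""fNIRS preprocessing chain: quality control, optical density, hybrid
motion correction, Beer-Lambert conversion, band-pass filtering and PCA
removal of global physiology.

The chain never alters sampling rate or channel identity except through the
documented quality-control removals.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.interpolate import make_smoothing_spline

from . import wavelets
from .extinction import extinction_matrix
from .types import (
    CohortDataset,
    InvalidArgumentError,
    InvalidDataError,
    TimeSeriesRun,
)

__all__ = [
    "QualityConfig",
    "MBLLConfig",
    "BandpassSpec",
    "SplineConfig",
    "WaveletConfig",
    "QCReport",
    "compute_channel_snr",
    "apply_quality_control",
    "intensity_to_od",
    "motion_correct_hybrid",
    "mbll",
    "bandpass",
    "pca_global_filter",
    "preprocess_intensity_pair",
]


@dataclass
class QualityConfig:
    snr_threshold: float = 8.0
    min_good_channel_fraction: float = 0.5
    consistent_bad_fraction: float = 0.7

    def __post_init__(self) -> None:
        if not self.snr_threshold > 0:
            raise InvalidArgumentError("snr_threshold must be positive")
        for name in ("min_good_channel_fraction", "consistent_bad_fraction"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise InvalidArgumentError(f"{name} must lie in (0, 1]")


@dataclass
class MBLLConfig:
    dpf: tuple[float, float] = (6.0, 6.0)
    wavelengths: tuple[float, float] = (760.0, 850.0)
    distances: float | np.ndarray = 3.0

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.dpf):
            raise InvalidArgumentError("dpf values must be positive")


@dataclass
class BandpassSpec:
    low_cut: float = 0.009
    high_cut: float = 0.08
    design: str = "butter"
    order: int = 3

    def validate(self, sampling_rate: float) -> None:
        if not 0 < self.low_cut < self.high_cut:
            raise InvalidArgumentError("need 0 < low_cut < high_cut")
        if self.high_cut >= sampling_rate / 2:
            raise InvalidArgumentError(
                f"high_cut {self.high_cut} Hz not below Nyquist "
                f"({sampling_rate / 2} Hz)"
            )
        if self.design != "butter":
            raise InvalidArgumentError(f"unknown filter design {self.design!r}")


@dataclass
class SplineConfig:
    """Spline stage of the hybrid motion correction.

    Artifact segments are where the moving standard deviation (window
    ``window_s`` seconds) exceeds ``threshold`` times the channel scale;
    ``robust=True`` uses the MAD-based scale so the artifacts themselves do
    not inflate the threshold. ``smoothing`` is the spline parameter p in
    (0, 1]; the fitted spline is subtracted inside each segment and segment
    baselines are re-levelled.
    """

    window_s: float = 1.0
    threshold: float = 3.0
    smoothing: float = 0.99
    robust: bool = True


@dataclass
class WaveletConfig:
    """Wavelet stage of the hybrid motion correction.

    Detail coefficients outside ``iqr_multiplier`` Tukey fences are zeroed,
    but only when they also exceed ``amplitude_floor`` times the channel's
    robust sd — motion artifacts dwarf the signal, whereas the Tukey fence
    alone would also clip sparse leakage coefficients of clean signals.
    """

    wavelet: str = "db2"
    level: int = 5
    iqr_multiplier: float = 1.5
    amplitude_floor: float = 0.5


@dataclass
class QCReport:
    """Every removal with its reason, in application order."""

    pruned_channels: list[dict] = field(default_factory=list)
    dropped_runs: list[dict] = field(default_factory=list)
    removed_channels: list[dict] = field(default_factory=list)

    @property
    def empty(self) -> bool:
        return not (self.pruned_channels or self.dropped_runs or self.removed_channels)

    def to_dict(self) -> dict:
        return {
            "pruned_channels": self.pruned_channels,
            "dropped_runs": self.dropped_runs,
            "removed_channels": self.removed_channels,
        }

    def summary(self) -> str:
        lines = [
            f"channels pruned (low SNR): {len(self.pruned_channels)}",
            f"runs dropped (<50% good channels): {len(self.dropped_runs)}",
            f"channels removed cohort-wide: {len(self.removed_channels)}",
        ]
        for entry in self.dropped_runs:
            lines.append(
                f"  dropped {entry['subject_id']}/{entry['run_id']}: "
                f"{entry['good_fraction']:.0%} good channels"
            )
        for entry in self.removed_channels:
            lines.append(
                f"  removed {entry['channel_id']}: bad in "
                f"{entry['bad_fraction']:.0%} of participants"
            )
        return "\n".join(lines)


def compute_channel_snr(run: TimeSeriesRun) -> np.ndarray:
    """Per-channel SNR = mean / sd on the raw series (sd = 0 -> +inf)."""
    if run.n_samples < 2:
        raise InvalidArgumentError("need at least 2 samples per channel")
    mean = run.data.mean(axis=1)
    sd = run.data.std(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        snr = np.where(sd == 0, np.inf, mean / np.where(sd == 0, 1.0, sd))
    return snr


def apply_quality_control(
    cohort: CohortDataset, qc: QualityConfig | None = None
) -> tuple[CohortDataset, QCReport]:
    """Three sequential passes.

    1. flag channels with SNR below threshold, per run group (a channel is
       bad if it fails in any contrast of that run);
    2. drop run groups whose good-channel fraction is below the minimum;
    3. remove, from everyone, channels flagged bad in more than
       ``consistent_bad_fraction`` of the surviving participants (bad for a
       participant = bad in at least one surviving run).
    """
    qc = qc or QualityConfig()
    if not cohort.runs:
        raise InvalidArgumentError("cohort is empty")
    report = QCReport()

    groups: dict[tuple[str, str], list[TimeSeriesRun]] = {}
    for run in cohort.runs:
        groups.setdefault((run.subject_id, run.run_id), []).append(run)

    # Pass 1: SNR pruning per run group.
    group_bad: dict[tuple[str, str], np.ndarray] = {}
    for key, runs in sorted(groups.items()):
        bad = np.zeros(runs[0].n_channels, dtype=bool)
        for run in runs:
            bad |= compute_channel_snr(run) < qc.snr_threshold
        group_bad[key] = bad
        for ci in np.flatnonzero(bad):
            report.pruned_channels.append(
                {
                    "subject_id": key[0],
                    "run_id": key[1],
                    "channel_id": runs[0].channel_ids[ci],
                    "reason": f"SNR < {qc.snr_threshold}",
                }
            )

    # Pass 2: run exclusion.
    surviving: dict[tuple[str, str], list[TimeSeriesRun]] = {}
    for key, runs in sorted(groups.items()):
        good_fraction = 1.0 - group_bad[key].mean()
        if good_fraction < qc.min_good_channel_fraction:
            report.dropped_runs.append(
                {
                    "subject_id": key[0],
                    "run_id": key[1],
                    "good_fraction": float(good_fraction),
                    "reason": f"good-channel fraction < {qc.min_good_channel_fraction}",
                }
            )
        else:
            surviving[key] = runs
    if not surviving:
        raise InvalidDataError("quality control removed every run in the cohort")

    # Pass 3: consistent bad channels across participants.
    subjects = sorted({key[0] for key in surviving})
    n_channels = next(iter(surviving.values()))[0].n_channels
    bad_per_subject = np.zeros((len(subjects), n_channels), dtype=bool)
    for si, subject in enumerate(subjects):
        for key in surviving:
            if key[0] == subject:
                bad_per_subject[si] |= group_bad[key]
    bad_fraction = bad_per_subject.mean(axis=0)
    remove = bad_fraction > qc.consistent_bad_fraction
    channel_ids = next(iter(surviving.values()))[0].channel_ids
    for ci in np.flatnonzero(remove):
        report.removed_channels.append(
            {
                "channel_id": channel_ids[ci],
                "bad_fraction": float(bad_fraction[ci]),
                "reason": f"bad in > {qc.consistent_bad_fraction:.0%} of participants",
            }
        )

    keep = np.flatnonzero(~remove)
    out = CohortDataset(signatures=dict(cohort.signatures))
    for key in sorted(surviving):
        for run in surviving[key]:
            new = run.select_channels(keep)
            new.quality_flags = ~group_bad[key][keep]
            out.runs.append(new)
    return out, report


def intensity_to_od(run: TimeSeriesRun, reference: str = "log_mean") -> TimeSeriesRun:
    """Convert raw intensity to optical density, OD = -ln(I / I_ref).

    ``reference='log_mean'`` (default) uses the per-channel geometric mean
    of the full run, making OD exactly the mean-centred log-intensity (and
    the intensity round trip exact); ``reference='mean'`` uses the
    arithmetic temporal mean.
    """
    data = run.data
    if np.any(data <= 0):
        ci, si = np.argwhere(data <= 0)[0]
        raise InvalidDataError(
            f"non-positive intensity in channel {run.channel_ids[ci]} "
            f"at sample {si}"
        )
    log_i = np.log(data)
    if reference == "log_mean":
        od = -(log_i - log_i.mean(axis=1, keepdims=True))
    elif reference == "mean":
        od = -(log_i - np.log(data.mean(axis=1, keepdims=True)))
    else:
        raise InvalidArgumentError(f"unknown OD reference {reference!r}")
    return run.copy_with(data=od)


def _moving_sd(x: np.ndarray, window: int) -> np.ndarray:
    """Centred moving standard deviation via cumulative sums."""
    n = len(x)
    window = min(max(window, 2), n)
    kernel = np.ones(window) / window
    m1 = np.convolve(x, kernel, mode="same")
    m2 = np.convolve(x * x, kernel, mode="same")
    return np.sqrt(np.maximum(m2 - m1 * m1, 0.0))


def _artifact_segments(mask: np.ndarray, gap: int) -> list[tuple[int, int]]:
    """Contiguous True runs, merging runs separated by less than ``gap``."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    segments: list[tuple[int, int]] = []
    start = prev = idx[0]
    for i in idx[1:]:
        if i - prev >= gap:
            segments.append((start, prev + 1))
            start = i
        prev = i
    segments.append((start, prev + 1))
    return segments


def _correct_channel_spline(y: np.ndarray, fs: float, cfg: SplineConfig) -> np.ndarray:
    window = max(2, int(round(cfg.window_s * fs)))
    # Detect on the first difference: steps and spikes are transient there,
    # so a sustained baseline shift cannot inflate its own threshold.
    dy = np.diff(y)
    msd = _moving_sd(dy, window)
    if cfg.robust:
        med = np.median(dy)
        scale = 1.4826 * np.median(np.abs(dy - med))
        if scale == 0:
            scale = dy.std()
    else:
        scale = dy.std()
    if scale == 0:
        return y
    mask = np.zeros(len(y), dtype=bool)
    mask[:-1] = msd > cfg.threshold * scale
    segments = _artifact_segments(mask, gap=window)
    if not segments:
        return y

    y = y.copy()
    pad = window // 2
    lam = (1.0 - cfg.smoothing) / cfg.smoothing
    n = len(y)
    for a, b in segments:
        a = max(0, a - pad)
        b = min(n, b + pad)
        seg = y[a:b]
        if len(seg) >= 8:
            t = np.arange(len(seg), dtype=float)
            trend = make_smoothing_spline(t, seg, lam=lam)(t)
        else:
            trend = np.full(len(seg), np.median(seg))
        residual = seg - trend
        if a > 0:
            baseline = np.median(y[max(0, a - window):a])
        elif b < n:
            baseline = np.median(y[b:min(n, b + window)])
        else:
            baseline = np.median(seg)
        y[a:b] = baseline + residual
        if b < n and a > 0:
            post = np.median(y[b:min(n, b + window)])
            y[b:] -= post - baseline
    return y


def _correct_channel_wavelet(y: np.ndarray, cfg: WaveletConfig) -> np.ndarray:
    n = len(y)
    # Symmetric extension keeps the periodized transform free of wrap-around
    # discontinuities at the record edges.
    y = np.concatenate([y, y[::-1]])
    robust_sd = 1.4826 * np.median(np.abs(y - np.median(y)))
    floor = cfg.amplitude_floor * robust_sd
    coeffs = wavelets.wavedec(y, cfg.wavelet, cfg.level)
    for d in coeffs[1:]:
        med = np.median(d)
        q1, q3 = np.percentile(d, [25, 75])
        fence = max(cfg.iqr_multiplier * (q3 - q1), floor)
        d[np.abs(d - med) > fence] = 0.0
    return wavelets.waverec(coeffs, cfg.wavelet)[:n]


def motion_correct_hybrid(
    od: TimeSeriesRun,
    spline: SplineConfig | None = None,
    wavelet: WaveletConfig | None = None,
) -> TimeSeriesRun:
    """Hybrid motion correction on optical density: spline, then wavelet.

    The spline stage detects high-moving-sd segments, removes a smoothing
    spline inside each and re-levels baselines (targets step shifts); the
    wavelet stage zeroes detail coefficients outside Tukey fences (targets
    residual spikes).
    """
    spline = spline or SplineConfig()
    wavelet = wavelet or WaveletConfig()
    min_len = 2 ** min(wavelet.level, 1) * len(
        wavelets._DB_FILTERS.get(wavelet.wavelet, np.zeros(4))
    )
    if od.n_samples < max(4, min_len):
        raise InvalidArgumentError("run too short for one wavelet decomposition level")
    data = np.empty_like(od.data)
    for ci in range(od.n_channels):
        y = _correct_channel_spline(od.data[ci], od.sampling_rate, spline)
        data[ci] = _correct_channel_wavelet(y, wavelet)
    return od.copy_with(data=data)


def mbll(
    od760: TimeSeriesRun,
    od850: TimeSeriesRun,
    cfg: MBLLConfig | None = None,
) -> tuple[TimeSeriesRun, TimeSeriesRun, TimeSeriesRun]:
    """Modified Beer-Lambert law: OD at two wavelengths -> HbO/HbR/HbT (uM).

    Per channel, solves the 2x2 system
    ``dOD_lambda = (eps_HbO * HbO + eps_HbR * HbR) * d * DPF_lambda``.
    """
    cfg = cfg or MBLLConfig()
    if od760.data.shape != od850.data.shape:
        raise InvalidArgumentError("OD runs must share shape")
    if list(od760.channel_ids) != list(od850.channel_ids):
        raise InvalidArgumentError("OD runs must share channel ids")
    n_channels = od760.n_channels
    ext = extinction_matrix(cfg.wavelengths)  # (2 wavelengths, 2 chromophores)
    d = np.broadcast_to(np.asarray(cfg.distances, dtype=float), (n_channels,))
    dpf = np.asarray(cfg.dpf, dtype=float)

    od = np.stack([od760.data, od850.data])  # (2, channels, samples)
    # per-channel system matrix M_c = diag(d_c * dpf) @ ext
    m = ext[None, :, :] * (d[:, None, None] * dpf[None, :, None])  # (ch, 2, 2)
    det = m[:, 0, 0] * m[:, 1, 1] - m[:, 0, 1] * m[:, 1, 0]
    if np.any(np.abs(det) < 1e-15):
        raise InvalidArgumentError("singular extinction system for some channel")
    inv = np.empty_like(m)
    inv[:, 0, 0] = m[:, 1, 1]
    inv[:, 0, 1] = -m[:, 0, 1]
    inv[:, 1, 0] = -m[:, 1, 0]
    inv[:, 1, 1] = m[:, 0, 0]
    inv /= det[:, None, None]
    conc_mm = np.einsum("cij,jcs->ics", inv, od)  # (2 chromophores, ch, samples)
    hbo_data = conc_mm[0] * 1000.0
    hbr_data = conc_mm[1] * 1000.0

    hbo = od760.copy_with(data=hbo_data, contrast="HbO")
    hbr = od760.copy_with(data=hbr_data, contrast="HbR")
    hbt = od760.copy_with(data=hbo_data + hbr_data, contrast="HbT")
    return hbo, hbr, hbt


def bandpass(run: TimeSeriesRun, spec: BandpassSpec | None = None) -> TimeSeriesRun:
    """Zero-phase Butterworth band-pass (forward-backward, DC removed)."""
    spec = spec or BandpassSpec()
    spec.validate(run.sampling_rate)
    sos = sps.butter(
        spec.order,
        [spec.low_cut, spec.high_cut],
        btype="bandpass",
        fs=run.sampling_rate,
        output="sos",
    )
    return run.copy_with(data=sps.sosfiltfilt(sos, run.data, axis=-1))


def _remove_first_pc(data: np.ndarray) -> np.ndarray:
    centered = data - data.mean(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    return centered - np.outer(u[:, 0] * s[0], vt[0])


def pca_global_filter(
    hbo: TimeSeriesRun, hbr: TimeSeriesRun
) -> tuple[TimeSeriesRun, TimeSeriesRun]:
    """Remove the first across-channel principal component, per chromophore.

    Recompute HbT downstream from the filtered pair.
    """
    for run in (hbo, hbr):
        if run.n_channels < 2:
            raise InvalidArgumentError("PCA global filter needs >= 2 channels")
    return (
        hbo.copy_with(data=_remove_first_pc(hbo.data)),
        hbr.copy_with(data=_remove_first_pc(hbr.data)),
    )


def preprocess_intensity_pair(
    i760: TimeSeriesRun,
    i850: TimeSeriesRun,
    *,
    mbll_cfg: MBLLConfig | None = None,
    band: BandpassSpec | None = None,
    spline: SplineConfig | None = None,
    wavelet: WaveletConfig | None = None,
    motion_correction: bool = True,
    pca_filter: bool = True,
) -> tuple[TimeSeriesRun, TimeSeriesRun, TimeSeriesRun]:
    """Full per-run chain: OD -> motion correction -> MBLL -> band-pass ->
    PCA global filter; HbT recomputed from the filtered pair."""
    od760 = intensity_to_od(i760)
    od850 = intensity_to_od(i850)
    if motion_correction:
        od760 = motion_correct_hybrid(od760, spline, wavelet)
        od850 = motion_correct_hybrid(od850, spline, wavelet)
    hbo, hbr, _ = mbll(od760, od850, mbll_cfg)
    hbo = bandpass(hbo, band)
    hbr = bandpass(hbr, band)
    if pca_filter:
        hbo, hbr = pca_global_filter(hbo, hbr)
    hbt = hbo.copy_with(data=hbo.data + hbr.data, contrast="HbT")
    return hbo, hbr, hbt
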