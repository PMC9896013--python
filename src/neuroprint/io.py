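"""Plain-text persistence: runs as delimited matrices with JSON sidecars,
FC matrices as labelled delimited text; optional minimal SNIRF (HDF5)
export/import for raw-intensity runs."""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .types import CohortDataset, FCMatrix, InvalidDataError, TimeSeriesRun


def run_basename(run: TimeSeriesRun) -> str:
    return f"{run.subject_id}_{run.run_id}_{run.contrast}"


def write_run(run: TimeSeriesRun, directory: str | Path, seed: int | None = None) -> Path:
    """One TSV per run (channels x samples) plus a JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    base = directory / run_basename(run)
    np.savetxt(base.with_suffix(".tsv"), run.data, delimiter="\t")
    sidecar = {
        "subject_id": run.subject_id,
        "run_id": run.run_id,
        "contrast": run.contrast,
        "sampling_rate": run.sampling_rate,
        "channel_ids": list(run.channel_ids),
        "quality_flags": [bool(f) for f in run.quality_flags],
    }
    if seed is not None:
        sidecar["seed"] = seed
    base.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return base.with_suffix(".tsv")


def read_run(tsv_path: str | Path) -> TimeSeriesRun:
    tsv_path = Path(tsv_path)
    sidecar_path = tsv_path.with_suffix(".json")
    if not sidecar_path.exists():
        raise InvalidDataError(f"missing sidecar for {tsv_path}")
    meta = json.loads(sidecar_path.read_text())
    data = np.atleast_2d(np.loadtxt(tsv_path, delimiter="\t"))
    return TimeSeriesRun(
        subject_id=meta["subject_id"],
        run_id=meta["run_id"],
        contrast=meta["contrast"],
        data=data,
        sampling_rate=meta["sampling_rate"],
        channel_ids=meta["channel_ids"],
        quality_flags=np.asarray(meta.get("quality_flags", [True] * data.shape[0])),
    )


def write_cohort(cohort: CohortDataset, directory: str | Path) -> list[Path]:
    return [write_run(run, directory) for run in cohort.runs]


def read_cohort(directory: str | Path) -> CohortDataset:
    directory = Path(directory)
    cohort = CohortDataset()
    for tsv in sorted(directory.glob("*.tsv")):
        if tsv.with_suffix(".json").exists():
            cohort.runs.append(read_run(tsv))
    if not cohort.runs:
        raise InvalidDataError(f"no runs found in {directory}")
    return cohort


def write_fc(fc: FCMatrix, directory: str | Path) -> Path:
    """FC matrix as delimited text with a label header + JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    base = directory / f"{fc.subject_id}_{fc.run_id}_{fc.contrast}_fc"
    frame = pd.DataFrame(fc.values, index=fc.labels, columns=fc.labels)
    frame.to_csv(base.with_suffix(".tsv"), sep="\t")
    base.with_suffix(".json").write_text(
        json.dumps(
            {
                "subject_id": fc.subject_id,
                "run_id": fc.run_id,
                "contrast": fc.contrast,
                "flagged_channels": list(fc.flagged_channels),
            },
            indent=1,
        )
    )
    return base.with_suffix(".tsv")


def read_fc(tsv_path: str | Path) -> FCMatrix:
    tsv_path = Path(tsv_path)
    meta = json.loads(tsv_path.with_suffix(".json").read_text())
    frame = pd.read_csv(tsv_path, sep="\t", index_col=0)
    return FCMatrix(
        values=frame.to_numpy(),
        labels=[str(c) for c in frame.columns],
        subject_id=meta["subject_id"],
        run_id=meta["run_id"],
        contrast=meta["contrast"],
        flagged_channels=tuple(meta.get("flagged_channels", ())),
    )


def read_fc_dir(directory: str | Path) -> list[FCMatrix]:
    directory = Path(directory)
    fcs = [read_fc(p) for p in sorted(directory.glob("*_fc.tsv"))]
    if not fcs:
        raise InvalidDataError(f"no FC matrices found in {directory}")
    return fcs


def write_snirf(
    i760: TimeSeriesRun, i850: TimeSeriesRun, path: str | Path
) -> Path:
    """Minimal SNIRF-style HDF5 export of a two-wavelength intensity pair."""
    import h5py

    path = Path(path)
    with h5py.File(path, "w") as fh:
        fh.create_dataset("formatVersion", data="1.0")
        nirs = fh.create_group("nirs")
        data = nirs.create_group("data1")
        stacked = np.vstack([i760.data, i850.data]).T  # time x measurements
        data.create_dataset("dataTimeSeries", data=stacked)
        data.create_dataset(
            "time", data=np.arange(i760.n_samples) / i760.sampling_rate
        )
        for mi in range(stacked.shape[1]):
            ml = data.create_group(f"measurementList{mi + 1}")
            channel = mi % i760.n_channels
            wavelength_index = mi // i760.n_channels + 1
            ml.create_dataset("sourceIndex", data=channel + 1)
            ml.create_dataset("detectorIndex", data=channel + 1)
            ml.create_dataset("wavelengthIndex", data=wavelength_index)
            ml.create_dataset("dataType", data=1)
        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.array([760.0, 850.0]))
        meta = nirs.create_group("metaDataTags")
        meta.create_dataset("SubjectID", data=i760.subject_id)
        meta.create_dataset("MeasurementDate", data="unknown")
        meta.create_dataset("RunID", data=i760.run_id)
    return path


def read_snirf(path: str | Path) -> tuple[TimeSeriesRun, TimeSeriesRun]:
    """Read back the minimal export written by :func:`write_snirf`."""
    import h5py

    with h5py.File(path, "r") as fh:
        data = fh["nirs/data1"]
        stacked = np.asarray(data["dataTimeSeries"]).T
        time = np.asarray(data["time"])
        sampling_rate = 1.0 / float(np.median(np.diff(time)))
        subject = fh["nirs/metaDataTags/SubjectID"][()]
        run_id = fh["nirs/metaDataTags/RunID"][()]
    if isinstance(subject, bytes):
        subject = subject.decode()
    if isinstance(run_id, bytes):
        run_id = run_id.decode()
    n_channels = stacked.shape[0] // 2
    channel_ids = [f"ch{i:02d}" for i in range(n_channels)]
    common = dict(
        subject_id=subject, run_id=run_id, sampling_rate=sampling_rate,
        channel_ids=channel_ids,
    )
    return (
        TimeSeriesRun(contrast="intensity_760", data=stacked[:n_channels], **common),
        TimeSeriesRun(contrast="intensity_850", data=stacked[n_channels:], **common),
    )
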