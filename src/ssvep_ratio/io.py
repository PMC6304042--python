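"""Plain-text interchange: long-format recording CSVs with JSON sidecars.

All tabular interchange is CSV (diffable, desk-scale volumes) with a JSON
metadata sidecar carrying the paradigm parameters and, for synthetic
cohorts, the generator ground truth.  Only single-channel data are
handled; multi-channel input is rejected explicitly rather than silently
averaged.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .paradigms import ParadigmSpec
from .spectral import TrialRecording
from .synthetic import GroundTruth

__all__ = [
    "write_cohort",
    "read_recordings",
    "write_paradigm",
    "read_paradigm",
    "RECORDING_COLUMNS",
]

RECORDING_COLUMNS = ("subject", "group", "contrast", "repetition",
                     "sample_index", "voltage")


def write_paradigm(paradigm: ParadigmSpec, path: Path) -> None:
    path = Path(path)
    path.write_text(json.dumps(dataclasses.asdict(paradigm), indent=2) + "\n")


def read_paradigm(path: Path) -> ParadigmSpec:
    d = json.loads(Path(path).read_text())
    d["contrast_levels"] = tuple(d["contrast_levels"])
    return ParadigmSpec(**d)


def write_cohort(
    recordings: Iterable[TrialRecording],
    paradigm: ParadigmSpec,
    out_dir: Path,
    truth: GroundTruth | None = None,
) -> tuple[Path, Path]:
    """Write recordings.csv (long format) and metadata.json to ``out_dir``.

    CSV columns: subject, group, contrast, repetition, sample_index,
    voltage.  Sweep trials store an empty contrast field.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / "recordings.csv"
    frames = []
    for rec in recordings:
        n = len(rec.samples)
        frames.append(pd.DataFrame({
            "subject": np.repeat(rec.subject_id, n),
            "group": np.repeat(rec.group, n),
            "contrast": np.repeat(rec.contrast, n),
            "repetition": np.repeat(rec.repetition, n),
            "sample_index": np.arange(n),
            "voltage": rec.samples,
        }))
    pd.concat(frames, ignore_index=True).to_csv(csv_path, index=False)
    meta = {
        "schema": "ssvep-ratio/recordings-v1",
        "paradigm": dataclasses.asdict(paradigm),
    }
    if truth is not None:
        meta["ground_truth"] = truth.to_dict()
    meta_path = out_dir / "metadata.json"
    meta_path.write_text(json.dumps(meta, indent=2) + "\n")
    return csv_path, meta_path


def read_recordings(path: Path, metadata: Path | None = None) -> list[TrialRecording]:
    """Read a long-format cohort CSV back into ``TrialRecording`` objects.

    ``path`` may be the directory written by :func:`write_cohort` or the
    CSV itself (with ``metadata`` pointing at the sidecar).  Schema
    violations raise with the offending columns named; trials whose sample
    count disagrees with the paradigm are reported individually.
    """
    path = Path(path)
    if path.is_dir():
        csv_path = path / "recordings.csv"
        metadata = path / "metadata.json"
    else:
        csv_path = path
    if metadata is None or not Path(metadata).exists():
        raise FileNotFoundError("metadata JSON sidecar is required")
    meta = json.loads(Path(metadata).read_text())
    pdict = meta.get("paradigm")
    if pdict is None:
        raise ValueError("metadata missing 'paradigm' block "
                         "(sampling_rate, stim_freq, ...)")
    pdict = dict(pdict)
    pdict["contrast_levels"] = tuple(pdict["contrast_levels"])
    paradigm = ParadigmSpec(**pdict)

    table = pd.read_csv(csv_path)
    missing = [c for c in RECORDING_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"recordings CSV missing required columns: {missing}")
    bad = table.index[~np.isfinite(table["voltage"])].tolist()
    if bad:
        raise ValueError(
            f"non-finite voltage values at CSV rows {[i + 2 for i in bad[:5]]}"
        )
    recordings = []
    expected = paradigm.n_samples
    for (subject, group, contrast, rep), sub in table.groupby(
            ["subject", "group", "contrast", "repetition"], dropna=False, sort=True):
        sub = sub.sort_values("sample_index")
        if len(sub) != expected:
            raise ValueError(
                f"trial subject={subject!r} contrast={contrast} repetition={rep} "
                f"is truncated: {len(sub)} samples, expected {expected}")
        recordings.append(TrialRecording(
            subject_id=str(subject), group=str(group),
            contrast=float(contrast) if pd.notna(contrast) else float("nan"),
            repetition=int(rep), sampling_rate=paradigm.sampling_rate,
            stim_freq=paradigm.stim_freq,
            samples=sub["voltage"].to_numpy(), paradigm=paradigm.name,
        ))
    return recordings
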