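"""Reading and writing spike-time tables, manifests, snippets and intensity tables.

On-disk conventions (one unambiguous unit per file):

* spike files: comma-delimited text with columns ``cell_id,event_type,time_s``
  (``event_type`` in {SS, CS}), times in seconds serialized with 6 decimals
  (microsecond resolution), so read(write(r)) == r exactly;
* manifests: JSON, one entry per cell with metadata and (for synthetic
  cohorts) the generator ground truth;
* waveform snippet tables: comma-delimited, first column ``time_ms``, one
  column per snippet;
* lobule intensity tables: comma-delimited ``lobule,soma_intensity,
  background_intensity`` (optionally one row per section).
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .types import SpikeTrainRecording

__all__ = [
    "write_recording",
    "read_recording",
    "write_manifest",
    "read_manifest",
    "write_population",
    "read_population",
    "write_snippets",
    "read_snippets",
    "read_intensity_table",
    "normalize_intensity",
    "canonical_lobule",
]

TIME_DECIMALS = 6

# Controlled lobule vocabulary (vermis lobules plus hemispheral regions);
# matching is case-insensitive and tolerant of dash variants.
LOBULE_VOCABULARY = [
    "I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X",
    "I-III", "II-V", "VIII-IX",
    "HIV&V-Sim", "CrI-II", "PM", "Cop-PF", "Flocc",
]
_CANONICAL = {v.lower().replace("–", "-"): v for v in LOBULE_VOCABULARY}


def canonical_lobule(label: str) -> Optional[str]:
    """Map a free-string lobule label onto the controlled vocabulary.

    Returns None when the label is not recognized.
    """
    key = str(label).strip().lower().replace("–", "-")
    return _CANONICAL.get(key)


# ---------------------------------------------------------------------------
# spike files + manifests
# ---------------------------------------------------------------------------

def write_recording(rec: SpikeTrainRecording, path) -> None:
    """Write one cell's spike table (cell_id,event_type,time_s; 6 decimals)."""
    path = Path(path)
    rows = [(rec.cell_id, "SS", t) for t in rec.ss_times]
    rows += [(rec.cell_id, "CS", t) for t in rec.cs_times]
    rows.sort(key=lambda r: r[2])
    with path.open("w") as fh:
        fh.write("cell_id,event_type,time_s\n")
        for cid, kind, t in rows:
            fh.write(f"{cid},{kind},{t:.{TIME_DECIMALS}f}\n")


def _manifest_entry(rec: SpikeTrainRecording) -> dict:
    entry = {
        "cell_id": rec.cell_id,
        "zebrin_identity": rec.zebrin_identity,
        "lobule": rec.lobule,
        "context": rec.context,
        "duration_s": rec.duration,
    }
    if rec.ground_truth is not None:
        entry["ground_truth"] = rec.ground_truth
    if rec.amplitude_series is not None:
        entry["amplitude_series"] = [[float(a), float(b)]
                                     for a, b in rec.amplitude_series]
    return entry


def read_recording(spike_file, manifest_entry: dict) -> SpikeTrainRecording:
    """Assemble a validated recording from a spike file and its manifest entry.

    Raises :class:`ValidationError` naming the offending row for unknown
    event types, unsorted times, or times outside [0, duration].
    """
    spike_file = Path(spike_file)
    duration = float(manifest_entry["duration_s"])
    ss: List[float] = []
    cs: List[float] = []
    with spike_file.open() as fh:
        header = fh.readline().strip().split(",")
        if header[:3] != ["cell_id", "event_type", "time_s"]:
            raise ValidationError(f"{spike_file}: unexpected header {header!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != 3:
                raise ValidationError(f"{spike_file}:{lineno}: expected 3 columns")
            _, kind, t_str = parts
            try:
                t = float(t_str)
            except ValueError:
                raise ValidationError(
                    f"{spike_file}:{lineno}: non-numeric time {t_str!r}") from None
            if not 0.0 <= t <= duration:
                raise ValidationError(
                    f"{spike_file}:{lineno}: time {t} outside [0, {duration}] s")
            if kind == "SS":
                ss.append(t)
            elif kind == "CS":
                cs.append(t)
            else:
                raise ValidationError(
                    f"{spike_file}:{lineno}: unknown event_type {kind!r}")
    for name, seq in (("ss_times", ss), ("cs_times", cs)):
        if any(b <= a for a, b in zip(seq, seq[1:])):
            raise ValidationError(
                f"{spike_file}: {name} not strictly increasing")
    amp = manifest_entry.get("amplitude_series")
    return SpikeTrainRecording(
        cell_id=manifest_entry["cell_id"],
        zebrin_identity=manifest_entry.get("zebrin_identity", "unknown"),
        lobule=manifest_entry.get("lobule", "unknown"),
        context=manifest_entry.get("context", "in_vivo"),
        duration=duration,
        ss_times=np.asarray(ss),
        cs_times=np.asarray(cs),
        amplitude_series=np.asarray(amp) if amp is not None else None,
        ground_truth=manifest_entry.get("ground_truth"),
    )


def write_manifest(manifest: dict, path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")


def read_manifest(path) -> dict:
    return json.loads(Path(path).read_text())


def write_population(recordings: Iterable[SpikeTrainRecording], out_dir,
                     manifest_extra: Optional[dict] = None) -> Path:
    """Write spike files plus a manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cells = []
    for rec in recordings:
        fname = f"{rec.cell_id}.csv"
        write_recording(rec, out_dir / fname)
        entry = _manifest_entry(rec)
        entry["spike_file"] = fname
        cells.append(entry)
    manifest = dict(manifest_extra or {})
    manifest["cells"] = cells
    mpath = out_dir / "manifest.json"
    write_manifest(manifest, mpath)
    return mpath


def read_population(manifest_path) -> List[SpikeTrainRecording]:
    manifest_path = Path(manifest_path)
    manifest = read_manifest(manifest_path)
    base = manifest_path.parent
    return [read_recording(base / e["spike_file"], e) for e in manifest["cells"]]


# ---------------------------------------------------------------------------
# waveform snippets
# ---------------------------------------------------------------------------

def write_snippets(time_ms: np.ndarray, snippets: np.ndarray, path) -> None:
    """Snippet table: first column time_ms, then one column per snippet."""
    snippets = np.atleast_2d(np.asarray(snippets, dtype=float))
    df = pd.DataFrame(snippets.T,
                      columns=[f"snippet_{i}" for i in range(snippets.shape[0])])
    df.insert(0, "time_ms", np.asarray(time_ms, dtype=float))
    df.to_csv(path, index=False, float_format="%.6g")


def read_snippets(path) -> Tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    if "time_ms" not in df.columns or df.shape[1] < 2:
        raise ValidationError(f"{path}: snippet table needs time_ms + snippet columns")
    time_ms = df["time_ms"].to_numpy()
    snippets = df.drop(columns="time_ms").to_numpy().T
    return time_ms, snippets


# ---------------------------------------------------------------------------
# zebrin intensity tables
# ---------------------------------------------------------------------------

def read_intensity_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"lobule", "soma_intensity", "background_intensity"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: intensity table missing columns {sorted(missing)}")
    return df


def normalize_intensity(table: pd.DataFrame) -> pd.DataFrame:
    """Per-lobule normalized zebrin staining intensity (soma / background).

    With several sections per lobule, the per-section ratios are averaged
    (ratio-then-average). The raw convention — high intensity = weak
    staining — is preserved as-is, never inverted.
    """
    for idx, row in table.iterrows():
        if not row["background_intensity"] > 0:
            raise ValidationError(
                f"intensity table row {idx} (lobule {row['lobule']!r}): "
                f"background must be > 0")
        if not row["soma_intensity"] > 0:
            raise ValidationError(
                f"intensity table row {idx} (lobule {row['lobule']!r}): "
                f"soma intensity must be > 0")
    df = table.copy()
    df["ratio"] = df["soma_intensity"] / df["background_intensity"]
    out = (df.groupby("lobule", sort=True)["ratio"].mean()
             .rename("normalized_intensity").reset_index())
    return out
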