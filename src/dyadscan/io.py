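"""Readers and writers: NIfTI volumes, BIDS-style event tables, behaviour
tables, and the run manifest that ties a dataset together."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from dyadscan.core import CONDITIONS, BoldRun, DyadscanError

__all__ = [
    "read_bold",
    "write_bold",
    "read_mask",
    "write_mask",
    "read_events",
    "write_events",
    "read_behavior",
    "write_behavior",
    "RunManifest",
    "SubjectEntry",
    "load_manifest",
]


def read_bold(path) -> BoldRun:
    """Load a 4-D NIfTI; TR is taken from the time-axis zoom."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise DyadscanError(f"{path}: expected a 4-D image, got ndim={data.ndim}")
    zooms = img.header.get_zooms()
    tr = float(zooms[3]) if len(zooms) > 3 else 0.0
    if tr <= 0:
        raise DyadscanError(f"{path}: TR missing from the header")
    return BoldRun(data, tr=tr, affine=np.asarray(img.affine))


def write_bold(run: BoldRun, path) -> None:
    img = nib.Nifti1Image(run.data, run.affine)
    zooms = list(img.header.get_zooms())
    zooms[3] = run.tr
    img.header.set_zooms(zooms)
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


def read_mask(path) -> np.ndarray:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise DyadscanError(f"{path}: expected a 3-D mask")
    return data > 0


def write_mask(mask: np.ndarray, affine, path) -> None:
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), np.asarray(affine))
    nib.save(img, str(path))


def read_events(path, whitelist=CONDITIONS) -> pd.DataFrame:
    """Read a BIDS-style events TSV (onset, duration, trial_type).

    Onsets are sorted (with a warning if they arrive unsorted); malformed
    numbers raise an error naming the offending line; labels outside the
    whitelist raise too.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"onset", "duration", "trial_type"}
    if not required.issubset(df.columns):
        raise DyadscanError(
            f"{path}: events file needs columns {sorted(required)}"
        )
    out_rows = []
    for i, row in df.iterrows():
        line_no = i + 2  # header is line 1
        try:
            onset = float(row["onset"])
            duration = float(row["duration"])
        except (TypeError, ValueError) as exc:
            raise DyadscanError(
                f"{path}: malformed onset/duration on line {line_no}"
            ) from exc
        if onset < 0:
            raise DyadscanError(f"{path}: negative onset on line {line_no}")
        if duration <= 0:
            raise DyadscanError(f"{path}: non-positive duration on line {line_no}")
        label = row["trial_type"]
        if whitelist is not None and label not in whitelist:
            raise DyadscanError(
                f"{path}: unknown trial_type {label!r} on line {line_no}"
            )
        out_rows.append((onset, duration, label))
    out = pd.DataFrame(out_rows, columns=["onset", "duration", "trial_type"])
    if len(out) and not out["onset"].is_monotonic_increasing:
        warnings.warn(f"{path}: onsets were not sorted; sorting")
        out = out.sort_values("onset", kind="stable").reset_index(drop=True)
    return out


def write_events(events: pd.DataFrame, path) -> None:
    events[["onset", "duration", "trial_type"]].to_csv(path, sep="\t", index=False)


def read_behavior(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"subject", "group", "condition", "accuracy"}
    if not required.issubset(df.columns):
        raise DyadscanError(f"{path}: behaviour table needs {sorted(required)}")
    acc = df["accuracy"].astype(float)
    if ((acc < 0) | (acc > 1)).any():
        raise DyadscanError(f"{path}: accuracy out of [0, 1]")
    return df


def write_behavior(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


@dataclass
class SubjectEntry:
    runs: list[str]
    events: list[str]
    group: str = ""
    scanner: str = ""
    partner: str = ""
    experiment: str = ""
    side: str = ""  # "A" or "B": which scanner of the dyad


@dataclass
class RunManifest:
    """Dataset inventory: per subject, run/event files and pairing info."""

    root: Path
    subjects: dict[str, SubjectEntry] = field(default_factory=dict)
    masks: dict[str, str] = field(default_factory=dict)

    def validate(self, check_files: bool = True) -> None:
        for sid, entry in self.subjects.items():
            if len(entry.runs) != len(entry.events):
                raise DyadscanError(f"{sid}: run/event file counts differ")
            if entry.partner:
                other = self.subjects.get(entry.partner)
                if other is None or other.partner != sid:
                    raise DyadscanError(
                        f"{sid}: partner relation is not symmetric"
                    )
            if check_files:
                for rel in list(entry.runs) + list(entry.events):
                    if not (self.root / rel).exists():
                        raise DyadscanError(f"{sid}: missing file {rel}")
        if check_files:
            for rel in self.masks.values():
                if not (self.root / rel).exists():
                    raise DyadscanError(f"missing mask file {rel}")

    def save(self, path) -> None:
        doc = {
            "subjects": {
                sid: {
                    "runs": list(e.runs),
                    "events": list(e.events),
                    "group": e.group,
                    "scanner": e.scanner,
                    "partner": e.partner,
                    "experiment": e.experiment,
                    "side": e.side,
                }
                for sid, e in self.subjects.items()
            },
            "masks": dict(self.masks),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)


def load_manifest(path, check_files: bool = True) -> RunManifest:
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "subjects" not in doc:
        raise DyadscanError(f"{path}: manifest needs a 'subjects' mapping")
    subjects = {
        sid: SubjectEntry(
            runs=list(e.get("runs", [])),
            events=list(e.get("events", [])),
            group=e.get("group", ""),
            scanner=e.get("scanner", ""),
            partner=e.get("partner", ""),
            experiment=e.get("experiment", ""),
            side=e.get("side", ""),
        )
        for sid, e in doc["subjects"].items()
    }
    manifest = RunManifest(
        root=path.parent, subjects=subjects, masks=dict(doc.get("masks", {}))
    )
    manifest.validate(check_files=check_files)
    return manifest
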