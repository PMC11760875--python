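"""Readers and writers for landmark data: TPS files and long-format CSV.

The TPS dialect covers the keys produced by the tpsUtil/tpsDig tool chain:
``LM=`` followed by whitespace-separated coordinate lines, then optional
``IMAGE=``, ``ID=`` and ``SCALE=`` records.  Keys are case-insensitive and
CRLF line endings are tolerated; a SCALE factor multiplies coordinates on
read.  Writers are deterministic (fixed six-decimal coordinates, fixed key
order), so files round-trip bit-exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .procrustes import LandmarkDataset

__all__ = ["TpsRecord", "TpsFormatError", "read_tps", "write_tps",
           "read_long_csv", "write_long_csv", "dataset_to_records",
           "records_to_dataset", "write_ground_truth"]

logger = logging.getLogger("sporemorph")

LANDMARK_LABELS = tuple(f"L{i}" for i in range(1, 9))


class TpsFormatError(ValueError):
    """Malformed TPS input."""


@dataclass
class TpsRecord:
    coords: np.ndarray
    image: str = ""
    id: str = ""
    scale: float | None = None

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 2 or len(coords) == 0:
            raise ValueError("coords must be a nonempty (k, 2) array")
        self.coords = coords

    @property
    def lm_count(self) -> int:
        return len(self.coords)


def read_tps(path) -> list[TpsRecord]:
    """Parse a TPS landmark file into a list of records.

    SCALE is applied multiplicatively to the stored coordinates.  Errors
    report 1-based line numbers.
    """
    path = Path(path)
    records: list[TpsRecord] = []
    pending: dict | None = None

    def finish(pending):
        if pending is None:
            return
        if len(pending["rows"]) != pending["lm"]:
            raise TpsFormatError(
                f"{path}:{pending['line']}: LM={pending['lm']} but "
                f"{len(pending['rows'])} coordinate rows found")
        coords = np.array(pending["rows"], dtype=float)
        if pending["scale"] is not None:
            coords = coords * pending["scale"]
        records.append(TpsRecord(coords=coords, image=pending["image"],
                                 id=pending["id"], scale=pending["scale"]))

    with open(path, "r", newline="") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            upper = line.upper()
            if upper.startswith("LM="):
                finish(pending)
                try:
                    lm = int(line[3:])
                except ValueError as exc:
                    raise TpsFormatError(
                        f"{path}:{lineno}: bad LM count {line[3:]!r}") from exc
                pending = {"lm": lm, "rows": [], "image": "", "id": "",
                           "scale": None, "line": lineno}
            elif upper.startswith("IMAGE="):
                if pending is None:
                    raise TpsFormatError(f"{path}:{lineno}: IMAGE= before LM=")
                pending["image"] = line[6:]
            elif upper.startswith("ID="):
                if pending is None:
                    raise TpsFormatError(f"{path}:{lineno}: ID= before LM=")
                pending["id"] = line[3:]
            elif upper.startswith("SCALE="):
                if pending is None:
                    raise TpsFormatError(f"{path}:{lineno}: SCALE= before LM=")
                try:
                    pending["scale"] = float(line[6:])
                except ValueError as exc:
                    raise TpsFormatError(
                        f"{path}:{lineno}: bad SCALE {line[6:]!r}") from exc
            else:
                if pending is None:
                    raise TpsFormatError(
                        f"{path}:{lineno}: coordinates before LM=")
                parts = line.split()
                if len(parts) != 2:
                    raise TpsFormatError(
                        f"{path}:{lineno}: expected two coordinates, got "
                        f"{line!r}")
                try:
                    pending["rows"].append((float(parts[0]), float(parts[1])))
                except ValueError as exc:
                    raise TpsFormatError(
                        f"{path}:{lineno}: non-numeric coordinate in "
                        f"{line!r}") from exc
    finish(pending)
    if not records:
        logger.warning("empty TPS file: %s", path)
    return records


def write_tps(records, path) -> None:
    """Write records in the canonical dialect (deterministic byte output)."""
    path = Path(path)
    lines: list[str] = []
    for i, rec in enumerate(records):
        if rec.lm_count == 0:
            raise ValueError(f"record {i}: zero landmarks")
        lines.append(f"LM={rec.lm_count}")
        for x, y in rec.coords:
            lines.append(f"{x:.6f} {y:.6f}")
        if rec.image:
            lines.append(f"IMAGE={rec.image}")
        lines.append(f"ID={rec.id if rec.id else i}")
        if rec.scale is not None:
            lines.append(f"SCALE={rec.scale:g}")
    path.write_text("\n".join(lines) + "\n")


_LONG_COLUMNS = ["specimen_id", "host_id", "replicate", "landmark", "x", "y"]


def write_long_csv(dataset: LandmarkDataset, path) -> None:
    """Write a dataset as long-format CSV (one row per landmark placement)."""
    m, r, k, _ = dataset.coords.shape
    rows = []
    for i in range(m):
        for j in range(r):
            for l in range(k):
                rows.append((dataset.specimen_id[i], dataset.host_id[i],
                             dataset.replicate_id[j], LANDMARK_LABELS[l],
                             dataset.coords[i, j, l, 0],
                             dataset.coords[i, j, l, 1]))
    pd.DataFrame(rows, columns=_LONG_COLUMNS).to_csv(path, index=False,
                                                     float_format="%.9g")


def read_long_csv(path) -> LandmarkDataset:
    """Read a long-format CSV into a validated ``LandmarkDataset``.

    Requires columns specimen_id, host_id, replicate, landmark, x, y with
    landmark labels L1..L8; duplicated or missing cells are errors.
    """
    df = pd.read_csv(path)
    missing_cols = [c for c in _LONG_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing columns {missing_cols}")
    bad = set(df["landmark"]) - set(LANDMARK_LABELS)
    if bad:
        raise ValueError(f"{path}: unknown landmark labels {sorted(bad)}")
    dup = df.duplicated(subset=["specimen_id", "replicate", "landmark"])
    if dup.any():
        first = df.loc[dup, ["specimen_id", "replicate", "landmark"]].iloc[0]
        raise ValueError(f"{path}: duplicate row for {tuple(first)}")

    specimens = list(dict.fromkeys(df["specimen_id"]))
    replicates = sorted(df["replicate"].unique())
    m, r, k = len(specimens), len(replicates), len(LANDMARK_LABELS)
    spec_pos = {s: i for i, s in enumerate(specimens)}
    rep_pos = {s: i for i, s in enumerate(replicates)}
    lm_pos = {s: i for i, s in enumerate(LANDMARK_LABELS)}

    coords = np.full((m, r, k, 2), np.nan)
    host = {}
    for row in df.itertuples(index=False):
        i = spec_pos[row.specimen_id]
        coords[i, rep_pos[row.replicate], lm_pos[row.landmark]] = (row.x, row.y)
        prev = host.setdefault(row.specimen_id, row.host_id)
        if prev != row.host_id:
            raise ValueError(
                f"{path}: conflicting host_id for specimen {row.specimen_id}")
    if np.isnan(coords).any():
        holes = [(specimens[i], replicates[j], LANDMARK_LABELS[l])
                 for i, j, l in zip(*np.nonzero(np.isnan(coords[..., 0])))]
        raise ValueError(f"{path}: missing cells {holes[:10]}"
                         + (" ..." if len(holes) > 10 else ""))
    return LandmarkDataset(
        coords=coords,
        host_id=np.array([host[s] for s in specimens]),
        specimen_id=np.array(specimens, dtype=object),
        replicate_id=np.array(replicates),
    )


def dataset_to_records(dataset: LandmarkDataset) -> list[TpsRecord]:
    """Flatten a dataset to TPS records (id encodes specimen and replicate)."""
    out = []
    for i in range(dataset.n_specimens):
        for j in range(dataset.n_replicates):
            out.append(TpsRecord(
                coords=dataset.coords[i, j],
                id=f"{dataset.specimen_id[i]}_rep{dataset.replicate_id[j]}",
                image=f"host{dataset.host_id[i]}"))
    return out


def records_to_dataset(records, host_id=None) -> LandmarkDataset:
    """Assemble single-replicate TPS records into a dataset."""
    coords = np.stack([r.coords for r in records])[:, None]
    m = len(records)
    if host_id is None:
        host_id = np.ones(m, dtype=int)
    return LandmarkDataset(
        coords=coords, host_id=np.asarray(host_id),
        specimen_id=np.array([r.id or str(i) for i, r in enumerate(records)],
                             dtype=object),
        replicate_id=np.array([1]))


def write_ground_truth(specimens, path) -> None:
    """Sidecar CSV with the generator's ground truth per specimen."""
    df = pd.DataFrame({
        "specimen_id": [f"spore_{i + 1:03d}" for i in range(len(specimens))],
        "host_id": specimens.host_id,
        "true_mode1": specimens.true_mode_scores[:, 0],
        "true_mode2": specimens.true_mode_scores[:, 1],
        "true_size_factor": specimens.true_sizes,
    })
    df.to_csv(path, index=False, float_format="%.9g")
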