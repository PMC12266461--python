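"""Reading and writing of peak lists, sample manifests and tabular outputs.

The normative input format is the comma-delimited ASCII peak list exported by
instrument batch-processing software: one ``m/z,intensity`` pair per line,
optionally preceded by header lines whose first token is not numeric.  An
mzML reader is provided as a secondary route emitting the same contract.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MANIFEST_COLUMNS = ["sample_id", "product_label", "type_label", "replicate_index", "path"]


class PeakListError(ValueError):
    """Raised for malformed or empty peak-list files."""


class ManifestError(ValueError):
    """Raised for schema or consistency problems in a sample manifest."""


@dataclass
class RawPeakList:
    """A centroided peak list: strictly increasing m/z with non-negative counts."""

    mz: np.ndarray
    intensity: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.size == 0:
            raise PeakListError(f"empty spectrum: {self.source_id or '<memory>'}")
        if self.mz.size != self.intensity.size:
            raise PeakListError("m/z and intensity lengths differ")
        if np.any(self.intensity < 0):
            raise PeakListError("negative intensity")
        if np.any(np.diff(self.mz) <= 0):
            raise PeakListError("m/z not strictly increasing; use from_arrays to canonicalize")

    @classmethod
    def from_arrays(cls, mz, intensity, source_id: str = "") -> "RawPeakList":
        """Build a canonical peak list: sort by m/z and sum duplicate positions."""
        mz = np.asarray(mz, dtype=float)
        intensity = np.asarray(intensity, dtype=float)
        if mz.size == 0:
            raise PeakListError(f"empty spectrum: {source_id or '<memory>'}")
        if np.any(intensity < 0):
            raise PeakListError("negative intensity")
        order = np.argsort(mz, kind="stable")
        mz, intensity = mz[order], intensity[order]
        uniq, inverse = np.unique(mz, return_inverse=True)
        summed = np.zeros_like(uniq)
        np.add.at(summed, inverse, intensity)
        return cls(uniq, summed, source_id)

    @property
    def total_intensity(self) -> float:
        return float(self.intensity.sum())

    def __len__(self) -> int:
        return int(self.mz.size)


def read_peaklist(path: str | Path) -> RawPeakList:
    """Read a comma-delimited ASCII peak list.

    Header lines (first comma-separated token not numeric) are skipped.
    Duplicate m/z rows are summed and rows are sorted ascending by m/z.
    """
    path = Path(path)
    mzs: list[float] = []
    counts: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = [f.strip() for f in line.split(",")]
            try:
                mz = float(fields[0])
            except ValueError:
                continue  # header / comment line
            if len(fields) < 2:
                raise PeakListError(f"{path}:{lineno}: expected 'm/z,intensity'")
            try:
                count = float(fields[1])
            except ValueError as exc:
                raise PeakListError(f"{path}:{lineno}: bad intensity {fields[1]!r}") from exc
            if count < 0:
                raise PeakListError(f"{path}:{lineno}: negative intensity {count}")
            mzs.append(mz)
            counts.append(count)
    if not mzs:
        raise PeakListError(f"empty spectrum: {path}")
    return RawPeakList.from_arrays(mzs, counts, source_id=str(path))


def write_peaklist(peaklist: RawPeakList, path: str | Path) -> None:
    """Write a peak list back to comma-delimited ASCII (round-trip safe)."""
    with open(path, "w") as fh:
        for mz, count in zip(peaklist.mz, peaklist.intensity):
            fh.write(f"{float(mz)!r},{float(count)!r}\n")


def read_mzml(path: str | Path) -> list[RawPeakList]:
    """Read centroided spectra from an mzML file (secondary input route)."""
    from pyteomics import mzml  # local import: optional heavy dependency path

    out = []
    with mzml.MzML(str(path)) as reader:
        for i, spec in enumerate(reader):
            out.append(
                RawPeakList.from_arrays(
                    spec["m/z array"], spec["intensity array"], source_id=f"{path}#{i}"
                )
            )
    if not out:
        raise PeakListError(f"no spectra in {path}")
    return out


@dataclass
class SampleManifest:
    """Table of (sample_id, product_label, type_label, replicate_index, path) rows."""

    table: pd.DataFrame
    source: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in MANIFEST_COLUMNS if c not in self.table.columns]
        if missing:
            raise ManifestError(f"manifest missing column(s): {missing}")
        dup = self.table.duplicated(subset=["sample_id", "replicate_index"])
        if dup.any():
            rows = self.table.loc[dup, ["sample_id", "replicate_index"]]
            raise ManifestError(f"duplicate (sample_id, replicate_index): {rows.values.tolist()}")

    @property
    def sample_ids(self) -> list[str]:
        return list(dict.fromkeys(self.table["sample_id"]))

    def replicate_counts(self) -> pd.Series:
        return self.table.groupby("sample_id", sort=False).size()

    def paths_for(self, sample_id: str) -> list[str]:
        sub = self.table[self.table["sample_id"] == sample_id]
        return list(sub.sort_values("replicate_index")["path"])

    def labels(self) -> pd.Series:
        """type_label per sample (first occurrence)."""
        return self.table.groupby("sample_id", sort=False)["type_label"].first()


def read_manifest(path: str | Path, check_paths: bool = True) -> SampleManifest:
    """Load and validate a CSV sample manifest.

    Fewer than 4 replicates for a sample is allowed but produces a warning
    (real studies retain at least 4 technical replicates per sample).
    """
    path = Path(path)
    table = pd.read_csv(path, dtype={"sample_id": str, "path": str})
    manifest = SampleManifest(table, source=str(path))
    if check_paths:
        for idx, row in table.iterrows():
            p = Path(row["path"])
            if not p.is_absolute():
                p = path.parent / p
            if not p.exists():
                raise ManifestError(f"manifest row {idx} (sample {row['sample_id']}): missing file {row['path']}")
    counts = manifest.replicate_counts()
    for sample_id, n in counts.items():
        logger.info("sample %s: %d replicate(s)", sample_id, n)
        if n < 4:
            warnings.warn(
                f"sample {sample_id} has fewer than 4 replicates ({n})", stacklevel=2
            )
    return manifest


# ---------------------------------------------------------------------------
# tabular / JSON output helpers shared by the CLI and scripts


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
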