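"""Beat-indexed multivariate series container and cohort I/O.

A :class:`BeatSeries` holds one subject-condition recording as an N-beat by
M-node table (default nodes R = respiration amplitude, H = heart period,
M = mean arterial pressure, C = arterial compliance).  Series are exchanged
on disk as plain comma-separated tables with an ``R,H,M,C`` header, one row
per beat; a cohort is described by a JSON manifest mapping subject ids to
per-condition file paths.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

MIN_BEATS = 50


@dataclass
class BeatSeries:
    """One subject-condition multivariate beat-to-beat series.

    Parameters
    ----------
    data
        N-beat by M-node frame; columns are node labels.
    subject_id, condition
        Identifiers used in exported tidy tables (condition is typically
        ``"REST"`` or ``"HUT"``).
    mean_beat_duration_s
        Mean beat length in seconds, needed to translate a cutoff given in
        Hz into cycles/beat.  Synthetic data uses 1.0 s.
    """

    data: pd.DataFrame
    subject_id: str = "S00"
    condition: str = "REST"
    mean_beat_duration_s: float = 1.0

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(np.asarray(self.data, dtype=float))
        self.data = self.data.astype(float)
        if self.data.isna().any().any():
            raise ValueError("beat series contains missing values")
        if len(self.data) < MIN_BEATS:
            raise ValueError(
                f"beat series has {len(self.data)} beats; at least {MIN_BEATS} required"
            )
        if len(set(self.data.columns)) != self.data.shape[1]:
            raise ValueError("node labels must be unique")
        if self.mean_beat_duration_s <= 0:
            raise ValueError("mean_beat_duration_s must be positive")

    # -- basic views ------------------------------------------------------
    @property
    def nodes(self) -> tuple[str, ...]:
        return tuple(self.data.columns)

    @property
    def n_beats(self) -> int:
        return len(self.data)

    @property
    def values(self) -> np.ndarray:
        """N x M float array (rows are beats)."""
        return self.data.to_numpy()

    def column(self, node: str) -> np.ndarray:
        return self.data[node].to_numpy()

    def with_values(self, values: np.ndarray) -> "BeatSeries":
        """Same metadata, new sample values (shape must match)."""
        values = np.asarray(values, dtype=float)
        if values.shape != self.data.shape:
            raise ValueError("replacement values must keep the series shape")
        return replace(self, data=pd.DataFrame(values, columns=self.data.columns))

    # -- disk format ------------------------------------------------------
    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.data.to_csv(path, index=False, float_format="%.10g")
        return path

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        subject_id: str = "S00",
        condition: str = "REST",
        mean_beat_duration_s: float = 1.0,
    ) -> "BeatSeries":
        return cls(
            pd.read_csv(path),
            subject_id=subject_id,
            condition=condition,
            mean_beat_duration_s=mean_beat_duration_s,
        )


def write_cohort(
    cohort: list[tuple[BeatSeries, BeatSeries]],
    out_dir: str | Path,
    ground_truth: dict | None = None,
) -> Path:
    """Write a paired cohort as CSV tables plus a JSON manifest.

    Returns the manifest path.  ``ground_truth``, if given, is written
    alongside as ``ground_truth.json``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, dict[str, str]] = {}
    for pair in cohort:
        for series in pair:
            fname = f"{series.subject_id}_{series.condition}.csv"
            series.to_csv(out_dir / fname)
            manifest.setdefault(series.subject_id, {})[series.condition] = fname
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    if ground_truth is not None:
        (out_dir / "ground_truth.json").write_text(
            json.dumps(ground_truth, indent=1, sort_keys=True)
        )
    return manifest_path


def read_cohort(manifest_path: str | Path) -> list[tuple[BeatSeries, ...]]:
    """Read a cohort manifest; returns one tuple of condition series per subject."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    manifest = json.loads(manifest_path.read_text())
    cohort = []
    for subject_id in sorted(manifest):
        entry = manifest[subject_id]
        pair = tuple(
            BeatSeries.from_csv(base / entry[cond], subject_id=subject_id, condition=cond)
            for cond in sorted(entry)
        )
        cohort.append(pair)
    return cohort
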