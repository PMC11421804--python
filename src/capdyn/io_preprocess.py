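"""Reading, writing, and frame-level preparation of parcellated BOLD time series.

A cohort lives on disk as plain tab-delimited matrices (frames x parcels, header
row = parcel IDs), one per subject/day/run, plus single-column FD files and a
TSV manifest mapping files to (subject_id, day, run).  Frame-level preparation
drops per-run dummy frames, removes the per-run per-parcel mean, reorders runs
into acquisition order, concatenates them, and derives a motion-scrubbing mask
from framewise displacement (FD).  Scrubbing is represented as a boolean mask,
never by deleting frames, so original frame indices stay addressable.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

#: Default framewise-displacement scrub threshold in mm.  Frames with
#: FD strictly greater than this are excluded; FD == threshold is kept.
DEFAULT_FD_THRESHOLD = 0.5

#: Default number of dummy frames removed from the start of every run.
DEFAULT_N_DUMMY = 100

#: Default acquisition-order permutation applied before concatenation
#: (1-based positions of the runs as stored in the manifest).
DEFAULT_RUN_ORDER = (2, 1, 4, 3)


class CohortFormatError(ValueError):
    """Raised when on-disk cohort files violate the expected format."""


@dataclasses.dataclass
class ParcelTimeSeries:
    """One subject-day of parcellated BOLD signal.

    Attributes
    ----------
    subject_id : str
        Opaque subject identifier.
    day : int
        Scan day, 1 or 2.
    data : ndarray, shape (n_frames, n_parcels)
        BOLD signal in arbitrary units.
    run_boundaries : list of (int, int)
        Half-open [start, end) frame intervals, disjoint, ordered,
        tiling [0, n_frames).
    fd : ndarray, shape (n_frames,)
        Framewise displacement per frame, mm.
    tr : float
        Sampling interval in seconds per frame.
    """

    subject_id: str
    day: int
    data: np.ndarray
    run_boundaries: list[tuple[int, int]]
    fd: np.ndarray
    tr: float = 0.72

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_parcels(self) -> int:
        return self.data.shape[1]

    def validate(self) -> None:
        if self.data.ndim != 2:
            raise CohortFormatError("data must be 2-D (frames x parcels)")
        if self.fd.shape != (self.n_frames,):
            raise CohortFormatError(
                f"fd length {self.fd.shape} does not match n_frames {self.n_frames}"
            )
        cursor = 0
        for start, end in self.run_boundaries:
            if start != cursor or end <= start:
                raise CohortFormatError(
                    f"run boundaries {self.run_boundaries} do not tile frames"
                )
            cursor = end
        if cursor != self.n_frames:
            raise CohortFormatError(
                f"run boundaries cover {cursor} frames, series has {self.n_frames}"
            )


@dataclasses.dataclass
class ScrubMask:
    """Per-frame keep/discard decision aligned to one ParcelTimeSeries."""

    keep: np.ndarray  # boolean, shape (n_frames,)

    @property
    def n_kept(self) -> int:
        return int(self.keep.sum())


def scrub_mask(ts: ParcelTimeSeries, fd_threshold: float = DEFAULT_FD_THRESHOLD) -> ScrubMask:
    """Mark frames with excessive motion.

    A frame is kept iff its FD is <= ``fd_threshold`` (strictly greater
    is scrubbed).  The mask is a pure function of the FD series.
    """
    fd = np.asarray(ts.fd, dtype=float)
    bad = ~np.isfinite(fd)
    if bad.any():
        idx = int(np.flatnonzero(bad)[0])
        raise ValueError(f"non-finite FD value at frame {idx} of subject {ts.subject_id}")
    return ScrubMask(keep=fd <= fd_threshold)


def preprocess_runs(
    ts: ParcelTimeSeries,
    n_dummy: int = DEFAULT_N_DUMMY,
    run_order: Sequence[int] | None = None,
) -> ParcelTimeSeries:
    """Drop dummy frames, demean each run, reorder and concatenate runs.

    Per run, the first ``n_dummy`` frames are removed from both the signal and
    the FD series; the per-parcel mean of each remaining run is subtracted;
    runs are then re-ordered according to ``run_order`` (1-based positions into
    the stored run list, default acquisition order 2-1-4-3 truncated/validated
    against the actual run count) and concatenated.

    Returns a new ParcelTimeSeries; the input is not modified.
    """
    ts.validate()
    n_runs = len(ts.run_boundaries)
    if run_order is None:
        run_order = DEFAULT_RUN_ORDER[:n_runs] if n_runs <= len(DEFAULT_RUN_ORDER) else None
        if run_order is None or sorted(run_order) != list(range(1, n_runs + 1)):
            run_order = tuple(range(1, n_runs + 1))
    run_order = tuple(int(r) for r in run_order)
    if len(run_order) == 0:
        raise ValueError("run_order must not be empty")
    if sorted(run_order) != list(range(1, n_runs + 1)):
        raise ValueError(
            f"run_order {run_order} is not a permutation of 1..{n_runs}"
        )

    pieces = []
    fd_pieces = []
    boundaries: list[tuple[int, int]] = []
    cursor = 0
    for pos in run_order:
        start, end = ts.run_boundaries[pos - 1]
        if end - start <= n_dummy:
            raise ValueError(
                f"run {pos} has {end - start} frames, not longer than n_dummy={n_dummy}"
            )
        block = ts.data[start + n_dummy : end].astype(float, copy=True)
        block -= block.mean(axis=0, keepdims=True)
        pieces.append(block)
        fd_pieces.append(ts.fd[start + n_dummy : end])
        boundaries.append((cursor, cursor + block.shape[0]))
        cursor += block.shape[0]

    return ParcelTimeSeries(
        subject_id=ts.subject_id,
        day=ts.day,
        data=np.concatenate(pieces, axis=0),
        run_boundaries=boundaries,
        fd=np.concatenate(fd_pieces),
        tr=ts.tr,
    )


# ---------------------------------------------------------------------------
# On-disk cohort format
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = ["subject_id", "day", "run", "path", "fd_path"]


def save_cohort(
    cohort: dict[tuple[str, int], ParcelTimeSeries],
    path: str | Path,
    subjects: pd.DataFrame | None = None,
) -> Path:
    """Write a cohort in the package's on-disk format.

    Each subject-day series is written run by run (one TSV matrix + one FD
    TSV per run) with a ``manifest.tsv`` tying them together and an optional
    ``subjects.tsv`` covariate table (subject_id, age, sex).
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    rows = []
    for (sid, day), ts in sorted(cohort.items()):
        ts.validate()
        parcel_ids = [f"p{j}" for j in range(ts.n_parcels)]
        for run_idx, (start, end) in enumerate(ts.run_boundaries, start=1):
            mat_name = f"{sid}_d{day}_r{run_idx}.tsv"
            fd_name = f"{sid}_d{day}_r{run_idx}_fd.tsv"
            pd.DataFrame(ts.data[start:end], columns=parcel_ids).to_csv(
                path / mat_name, sep="\t", index=False
            )
            pd.DataFrame({"fd": ts.fd[start:end]}).to_csv(
                path / fd_name, sep="\t", index=False
            )
            rows.append(
                {"subject_id": sid, "day": day, "run": run_idx,
                 "path": mat_name, "fd_path": fd_name}
            )
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(
        path / "manifest.tsv", sep="\t", index=False
    )
    if subjects is not None:
        subjects.to_csv(path / "subjects.tsv", sep="\t", index=False)
    return path


def load_cohort(
    path: str | Path,
) -> tuple[dict[tuple[str, int], ParcelTimeSeries], pd.DataFrame | None]:
    """Load a cohort directory written by :func:`save_cohort`.

    Returns ``(cohort, subjects)`` where ``cohort`` maps (subject_id, day) to
    a ParcelTimeSeries with runs concatenated in manifest order, and
    ``subjects`` is the covariate table or None.  Parcel counts must agree
    across all files; FD files are mandatory.
    """
    path = Path(path)
    manifest = pd.read_csv(path / "manifest.tsv", sep="\t", dtype={"subject_id": str})
    missing = set(MANIFEST_COLUMNS) - set(manifest.columns)
    if missing:
        raise CohortFormatError(f"manifest missing columns: {sorted(missing)}")

    cohort: dict[tuple[str, int], ParcelTimeSeries] = {}
    n_parcels: int | None = None
    grouped = manifest.sort_values(["subject_id", "day", "run"]).groupby(
        ["subject_id", "day"], sort=True
    )
    for (sid, day), grp in grouped:
        blocks, fds, boundaries = [], [], []
        cursor = 0
        for _, row in grp.iterrows():
            mat = pd.read_csv(path / row["path"], sep="\t").to_numpy(dtype=float)
            if n_parcels is None:
                n_parcels = mat.shape[1]
            elif mat.shape[1] != n_parcels:
                raise CohortFormatError(
                    f"{row['path']} has {mat.shape[1]} parcels, cohort has {n_parcels}"
                )
            fd_file = path / row["fd_path"]
            if not fd_file.exists():
                raise CohortFormatError(f"missing FD file {row['fd_path']}")
            fd_tab = pd.read_csv(fd_file, sep="\t")
            if "fd" not in fd_tab.columns:
                raise CohortFormatError(f"{row['fd_path']} lacks an 'fd' column")
            fd = fd_tab["fd"].to_numpy(dtype=float)
            if fd.shape[0] != mat.shape[0]:
                raise CohortFormatError(
                    f"{row['fd_path']}: FD length {fd.shape[0]} != frames {mat.shape[0]}"
                )
            blocks.append(mat)
            fds.append(fd)
            boundaries.append((cursor, cursor + mat.shape[0]))
            cursor += mat.shape[0]
        ts = ParcelTimeSeries(
            subject_id=str(sid),
            day=int(day),
            data=np.concatenate(blocks, axis=0),
            run_boundaries=boundaries,
            fd=np.concatenate(fds),
        )
        ts.validate()
        cohort[(str(sid), int(day))] = ts

    subjects_file = path / "subjects.tsv"
    subjects = (
        pd.read_csv(subjects_file, sep="\t", dtype={"subject_id": str})
        if subjects_file.exists()
        else None
    )
    return cohort, subjects
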