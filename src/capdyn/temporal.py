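"""Per-subject temporal CAP measures: fractional occupancy and dwell time.

Frames surviving motion scrubbing are assigned to CAP states (nearest
centroid, or maximum spatial correlation against a basis set), run-length
encoded into dwell segments, and summarized per subject-day as

* fractional occupancy FO(i): kept frames in state i / all kept frames
  (sums to 1 over states within a subject-day);
* mean DT(i): mean length in TR of consecutive same-state segments;
* var DT(i): standard deviation of those segment lengths (population SD by
  default, so a single segment yields 0).

Scrubbing is applied before segment extraction, so frames on either side of
a scrubbed gap merge into one segment when they share a state — shortening
or lengthening dwell estimates exactly as a post-scrub run-length encoding
implies.  Segments never span a day; by default they also break at run
boundaries (runs are not contiguous in time).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .io_preprocess import ParcelTimeSeries, ScrubMask

METRIC_NAMES = ("fo", "mean_dt", "var_dt")


@dataclasses.dataclass
class StateSequence:
    """Per-kept-frame CAP labels for one subject-day (scrubbed frames absent)."""

    subject_id: str
    day: int
    labels: np.ndarray            # int cluster/basis indices, kept frames only
    kept_frame_indices: np.ndarray
    run_ids: np.ndarray           # run index of each kept frame
    source: tuple = (None, None)  # (permutation_id, split_id)

    def __len__(self) -> int:
        return len(self.labels)


def assign_frames(
    ts: ParcelTimeSeries,
    mask: ScrubMask,
    centroids: np.ndarray,
    mode: str = "cluster",
    source: tuple = (None, None),
) -> tuple[StateSequence, np.ndarray | None]:
    """Assign kept frames to CAP states.

    mode="cluster": nearest centroid in Euclidean distance (the k-means
    criterion).  mode="correlation": maximum Pearson correlation against
    (basis) patterns; the per-frame maximum r is returned as the second
    element.  Zero-variance frames, whose correlation is undefined, fall
    back to the Euclidean rule and are assigned r = NaN.
    """
    centroids = np.asarray(centroids, dtype=float)
    if centroids.shape[1] != ts.n_parcels:
        raise ValueError(
            f"centroids have {centroids.shape[1]} parcels, series has {ts.n_parcels}"
        )
    keep = np.asarray(mask.keep, dtype=bool)
    frames = ts.data[keep]
    kept_idx = np.flatnonzero(keep)
    run_ids = np.empty(ts.n_frames, dtype=np.int64)
    for r, (start, end) in enumerate(ts.run_boundaries):
        run_ids[start:end] = r

    # Euclidean distances (used by both modes; correlation mode as fallback)
    d2 = (
        (frames ** 2).sum(axis=1)[:, None]
        - 2.0 * frames @ centroids.T
        + (centroids ** 2).sum(axis=1)[None, :]
    )
    euclid = np.argmin(d2, axis=1)

    max_r: np.ndarray | None = None
    if mode == "cluster":
        labels = euclid
    elif mode == "correlation":
        fc = frames - frames.mean(axis=1, keepdims=True)
        cc = centroids - centroids.mean(axis=1, keepdims=True)
        f_norm = np.linalg.norm(fc, axis=1)
        c_norm = np.linalg.norm(cc, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (fc @ cc.T) / (f_norm[:, None] * c_norm[None, :])
        r_safe = np.nan_to_num(r, nan=-2.0)
        labels = np.where(f_norm > 0, np.argmax(r_safe, axis=1), euclid)
        max_r = np.where(f_norm > 0, r_safe.max(axis=1), np.nan)
        if (f_norm == 0).any():
            warnings.warn(
                f"{int((f_norm == 0).sum())} zero-variance frames assigned by "
                "Euclidean fallback", stacklevel=2,
            )
    else:
        raise ValueError(f"unknown assignment mode {mode!r}")

    seq = StateSequence(
        subject_id=ts.subject_id, day=ts.day, labels=labels.astype(np.int64),
        kept_frame_indices=kept_idx, run_ids=run_ids[keep], source=source,
    )
    return seq, max_r


def extract_segments(seq: StateSequence, break_at_runs: bool = True
                     ) -> list[tuple[int, int]]:
    """Run-length encode the kept-frame label sequence into (label, length).

    Because scrubbed frames are absent from the sequence, same-state frames
    on both sides of a scrubbed gap fuse into one segment.  With
    ``break_at_runs`` (default), a segment ends at a run boundary even if
    the state continues.
    """
    labels = seq.labels
    if len(labels) == 0:
        return []
    breaks = labels[1:] != labels[:-1]
    if break_at_runs:
        breaks = breaks | (seq.run_ids[1:] != seq.run_ids[:-1])
    cut = np.flatnonzero(breaks) + 1
    segments = []
    start = 0
    for end in list(cut) + [len(labels)]:
        segments.append((int(labels[start]), end - start))
        start = end
    return segments


def compute_metrics(
    seq: StateSequence,
    n_states: int,
    break_at_runs: bool = True,
    ddof: int = 0,
) -> pd.DataFrame:
    """FO, mean DT, var DT and segment count per state for one subject-day.

    States in ``range(n_states)`` never visited get all-zero rows.  ``ddof=0``
    (population SD) makes a single segment yield var_dt = 0 rather than NaN.
    """
    rows = []
    segments = extract_segments(seq, break_at_runs=break_at_runs)
    total = len(seq)
    if total == 0:
        warnings.warn(
            f"empty state sequence for subject {seq.subject_id} day {seq.day}; "
            "all metrics zero", stacklevel=2,
        )
    seg_by_state: dict[int, list[int]] = {}
    for label, length in segments:
        seg_by_state.setdefault(label, []).append(length)
    for state in range(n_states):
        lengths = np.asarray(seg_by_state.get(state, []), dtype=float)
        if lengths.size == 0 or total == 0:
            fo = mean_dt = var_dt = 0.0
            n_seg = 0
        else:
            fo = lengths.sum() / total
            mean_dt = float(lengths.mean())
            var_dt = float(lengths.std(ddof=ddof)) if lengths.size > ddof else 0.0
            n_seg = int(lengths.size)
        rows.append({
            "subject_id": seq.subject_id, "day": seq.day, "state": state,
            "fo": fo, "mean_dt": mean_dt, "var_dt": var_dt, "n_segments": n_seg,
        })
    return pd.DataFrame(rows)


def aggregate_metrics(per_permutation: pd.DataFrame) -> pd.DataFrame:
    """Permutation-average temporal metrics per subject x day x CAP label.

    ``per_permutation`` is a tidy frame with columns subject_id, day,
    cap_label, fo, mean_dt, var_dt, n_segments, permutation, split, k_hat —
    one row per subject-day-CAP per permutation in which the subject appears,
    with CAP labels already matched to the basis set.

    Two averages are emitted for every cell:

    * ``*`` columns — mean over all permutations containing the subject,
      counting a CAP absent from a solution (e.g. CAP III in a 4-CAP split)
      as zeros: the feature-matrix convention.
    * ``*_present`` columns — mean over only the permutations whose solution
      actually contained that CAP label: the reliability convention for the
      extra state.

    Returns a tidy frame keyed (subject_id, day, cap_label) with both
    variants plus contributing-permutation counts.
    """
    df = per_permutation.copy()
    labels = sorted(df["cap_label"].unique())
    n_perm_by_subject = (
        df.groupby(["subject_id", "day"])["permutation"].nunique()
        .rename("n_perm_total")
    )
    # full grid: every (subject, day, permutation) x label, zeros where absent
    key = ["subject_id", "day", "permutation"]
    grid = df[key].drop_duplicates()
    full = (
        grid.merge(pd.DataFrame({"cap_label": labels}), how="cross")
        .merge(df, on=key + ["cap_label"], how="left")
    )
    value_cols = ["fo", "mean_dt", "var_dt", "n_segments"]
    full[value_cols] = full[value_cols].fillna(0.0)

    with_zeros = (
        full.groupby(["subject_id", "day", "cap_label"])[value_cols]
        .mean().reset_index()
    )
    present = (
        df.groupby(["subject_id", "day", "cap_label"])[value_cols]
        .mean().reset_index()
        .rename(columns={c: f"{c}_present" for c in value_cols})
    )
    n_present = (
        df.groupby(["subject_id", "day", "cap_label"])["permutation"]
        .nunique().rename("n_perm_present").reset_index()
    )
    out = (
        with_zeros.merge(present, on=["subject_id", "day", "cap_label"], how="left")
        .merge(n_present, on=["subject_id", "day", "cap_label"], how="left")
        .merge(n_perm_by_subject.reset_index(), on=["subject_id", "day"], how="left")
    )
    pres_cols = [f"{c}_present" for c in value_cols]
    out[pres_cols] = out[pres_cols].fillna(0.0)
    out["n_perm_present"] = out["n_perm_present"].fillna(0).astype(int)
    return out
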