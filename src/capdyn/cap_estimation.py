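"""Split-half permutation engine for CAP discovery.

Each permutation randomly splits the cohort's subjects into two disjoint
equal-size halves (one subject dropped when N is odd).  Within a split, the
scrub-surviving frames of all member subjects (both days) are temporally
concatenated, clustered with Lloyd's k-means (k-means++ initialization,
max_iter 1000) for every k in a scan range, and scored by the mean
silhouette.  The number of CAPs k̂ for that split is the elbow of the
silhouette-vs-k curve (a normalized-distance knee rule; argmax fallback when
the curve has no knee).  Per-subject per-day temporal metrics are computed
from the k̂ solution's frame assignments and kept in a ledger alongside the
centroids; per-frame assignments are not persisted.

All randomness derives from one base seed via ``numpy.random.SeedSequence``
spawning, so permutations are independent and order-invariant.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .io_preprocess import ParcelTimeSeries, scrub_mask, DEFAULT_FD_THRESHOLD
from .temporal import StateSequence, compute_metrics

logger = logging.getLogger(__name__)

DEFAULT_K_RANGE = range(2, 16)
DEFAULT_SILHOUETTE_SUBSAMPLE = 2000
KMEANS_MAX_ITER = 1000
KMEANS_TOL = 1e-4


@dataclasses.dataclass
class CapSet:
    """Cluster centroids (co-activation per parcel) from one k-means solution."""

    centroids: np.ndarray          # k x P
    k: int
    provenance: tuple              # (permutation_id, split_id, seed)
    inertia: float
    frame_counts: np.ndarray       # kept frames per cluster


@dataclasses.dataclass
class KScanResult:
    """k-means solutions and silhouettes over a contiguous k range."""

    capsets: dict[int, CapSet]
    silhouettes: dict[int, float]
    k_hat: int | None = None


@dataclasses.dataclass
class SplitResult:
    subject_ids: list[str]
    scan: KScanResult
    metrics: pd.DataFrame                       # cluster-index temporal metrics
    matched_labels: dict[int, str] | None = None  # filled by basis matching

    @property
    def k_hat(self) -> int:
        return self.scan.k_hat

    @property
    def capset(self) -> CapSet:
        return self.scan.capsets[self.scan.k_hat]


@dataclasses.dataclass
class PermutationRecord:
    permutation_id: int
    splits: list[SplitResult]
    excluded_subject: str | None = None
    error: str | None = None


@dataclasses.dataclass
class PermutationLedger:
    """All permutation results; failed permutations stay recorded."""

    records: list[PermutationRecord]
    k_range: tuple[int, ...]
    base_seed: int

    def iter_splits(self, failed: bool = False):
        for rec in self.records:
            if rec.error is not None and not failed:
                continue
            for split_id, split in enumerate(rec.splits):
                yield rec.permutation_id, split_id, split

    def k_hat_counts(self) -> dict[int, int]:
        counts: dict[int, int] = {}
        for _, _, split in self.iter_splits():
            counts[split.k_hat] = counts.get(split.k_hat, 0) + 1
        return counts

    @property
    def n_failed(self) -> int:
        return sum(1 for r in self.records if r.error is not None)


def split_half(subject_ids, rng: np.random.Generator | int
               ) -> tuple[list[str], list[str], str | None]:
    """Random disjoint equal halves; one uniformly chosen subject out if N odd."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    ids = list(subject_ids)
    if len(ids) < 4:
        raise ValueError("need at least 4 subjects for a split-half")
    perm = rng.permutation(len(ids))
    excluded = None
    if len(ids) % 2 == 1:
        excluded = ids[perm[-1]]
        perm = perm[:-1]
    half = len(perm) // 2
    split1 = [ids[i] for i in perm[:half]]
    split2 = [ids[i] for i in perm[half:]]
    return split1, split2, excluded


def scan_k(
    pooled_frames: np.ndarray,
    k_range=DEFAULT_K_RANGE,
    seed: int | np.random.SeedSequence = 0,
    silhouette_subsample: int | None = DEFAULT_SILHOUETTE_SUBSAMPLE,
    provenance: tuple = (None, None),
    return_labels: bool = False,
    n_init: int = 3,
):
    """k-means scan over ``k_range`` with mean-silhouette scoring.

    Lloyd's algorithm with k-means++ initialization (``n_init`` restarts,
    best inertia kept), max 1000 iterations, tolerance 1e-4 on inertia.
    Silhouettes are computed on a seeded uniform subsample (all frames when
    the pool is smaller).  An empty cluster triggers a re-run from a freshly
    derived seed (at most 5 retries).  Returns a KScanResult (k̂ unset),
    plus per-k label arrays when ``return_labels``.
    """
    X = np.asarray(pooled_frames, dtype=float)
    k_list = sorted(int(k) for k in k_range)
    if X.shape[0] < max(k_list) * 10:
        raise ValueError(
            f"{X.shape[0]} pooled frames is too few for k up to {max(k_list)}"
        )
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    child_seeds = ss.generate_state(2 * len(k_list) * 6, dtype=np.uint32)

    capsets: dict[int, CapSet] = {}
    silhouettes: dict[int, float] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    for ki, k in enumerate(k_list):
        fit = None
        for attempt in range(6):
            rs = int(child_seeds[ki * 6 + attempt] % (2**31 - 1))
            km = KMeans(
                n_clusters=k, init="k-means++", n_init=n_init,
                max_iter=KMEANS_MAX_ITER, tol=KMEANS_TOL,
                algorithm="lloyd", random_state=rs,
            ).fit(X)
            counts = np.bincount(km.labels_, minlength=k)
            if (counts > 0).all():
                fit = km
                break
            logger.warning("empty cluster at k=%d attempt %d; retrying", k, attempt)
        if fit is None:
            raise RuntimeError(f"k-means produced an empty cluster at k={k} after 5 retries")
        capsets[k] = CapSet(
            centroids=fit.cluster_centers_.copy(), k=k,
            provenance=(*provenance, rs), inertia=float(fit.inertia_),
            frame_counts=np.bincount(fit.labels_, minlength=k),
        )
        sil_seed = int(child_seeds[len(k_list) * 6 + ki * 6] % (2**31 - 1))
        sample = (None if silhouette_subsample is None
                  or X.shape[0] <= silhouette_subsample else silhouette_subsample)
        silhouettes[k] = float(
            silhouette_score(X, fit.labels_, sample_size=sample, random_state=sil_seed)
        )
        if return_labels:
            labels_by_k[k] = fit.labels_.copy()

    result = KScanResult(capsets=capsets, silhouettes=silhouettes)
    return (result, labels_by_k) if return_labels else result


def estimate_k(silhouette_by_k: dict[int, float]) -> int:
    """Elbow of the silhouette-vs-k curve.

    With k and silhouette range-normalized to [0, 1], the knee is the
    interior point with the largest positive excess above the chord joining
    the curve's endpoints (``y + x - 1`` for a decreasing curve) — the last
    point before the sharp drop.  Ties break toward smaller k.  A curve with
    no point above the chord (e.g. strictly linear decline) has no knee and
    falls back to the silhouette argmax, with a warning.
    """
    ks = np.array(sorted(silhouette_by_k), dtype=float)
    ys = np.array([silhouette_by_k[int(k)] for k in ks], dtype=float)
    if len(ks) < 3 or not np.isfinite(ys).all():
        raise ValueError("need >= 3 finite silhouette scores to locate a knee")
    x = (ks - ks[0]) / (ks[-1] - ks[0])
    y_range = ys.max() - ys.min()
    if y_range == 0:
        warnings.warn("flat silhouette curve; falling back to smallest k", stacklevel=2)
        return int(ks[0])
    y = (ys - ys.min()) / y_range
    # excess above the endpoint chord of the normalized decreasing curve;
    # the knee is the FIRST local maximum of the excess (later bumps in a
    # noisy tail are not knees)
    excess = y + x - 1.0
    for i in range(1, len(ks) - 1):
        if excess[i] > 1e-12 and excess[i] >= excess[i - 1] and excess[i] >= excess[i + 1]:
            return int(ks[i])
    warnings.warn(
        "no knee detected in silhouette curve; falling back to argmax", stacklevel=2
    )
    return int(ks[int(np.argmax(ys))])


def _pool_split_frames(
    cohort: dict[tuple[str, int], ParcelTimeSeries],
    subject_ids: list[str],
    fd_threshold: float,
) -> tuple[np.ndarray, list[tuple[str, int, np.ndarray, np.ndarray, int, int]]]:
    """Concatenate kept frames of the split's subjects (both days).

    Returns the pooled array plus per subject-day spans
    (sid, day, kept_frame_indices, run_ids, start, end) into the pool.
    """
    blocks, spans = [], []
    cursor = 0
    for sid in subject_ids:
        for day in (1, 2):
            ts = cohort[(sid, day)]
            keep = scrub_mask(ts, fd_threshold).keep
            frames = ts.data[keep]
            run_ids = np.empty(ts.n_frames, dtype=np.int64)
            for r, (s, e) in enumerate(ts.run_boundaries):
                run_ids[s:e] = r
            blocks.append(frames)
            spans.append((sid, day, np.flatnonzero(keep), run_ids[keep],
                          cursor, cursor + frames.shape[0]))
            cursor += frames.shape[0]
    return np.concatenate(blocks, axis=0), spans


def run_permutations(
    cohort: dict[tuple[str, int], ParcelTimeSeries],
    n_perm: int,
    k_range=DEFAULT_K_RANGE,
    base_seed: int = 0,
    fd_threshold: float = DEFAULT_FD_THRESHOLD,
    silhouette_subsample: int | None = DEFAULT_SILHOUETTE_SUBSAMPLE,
    break_at_runs: bool = True,
) -> PermutationLedger:
    """Run the full shuffled split-half resampling.

    For every permutation: split subjects, pool each split's scrub-masked
    frames, scan k, pick k̂, and compute per-subject-day temporal metrics
    from the k̂ solution's own frame assignments.  A failed permutation is
    recorded with its error rather than silently dropped.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    subject_ids = sorted({sid for sid, _ in cohort})
    root = np.random.SeedSequence(base_seed)
    records: list[PermutationRecord] = []
    for p in range(n_perm):
        perm_ss = np.random.SeedSequence(entropy=base_seed, spawn_key=(p,))
        rng = np.random.default_rng(perm_ss)
        try:
            split1, split2, excluded = split_half(subject_ids, rng)
            splits: list[SplitResult] = []
            for split_id, members in enumerate((split1, split2)):
                pooled, spans = _pool_split_frames(cohort, members, fd_threshold)
                scan, labels_by_k = scan_k(
                    pooled, k_range,
                    seed=np.random.SeedSequence(entropy=base_seed,
                                                spawn_key=(p, split_id)),
                    silhouette_subsample=silhouette_subsample,
                    provenance=(p, split_id), return_labels=True,
                )
                scan.k_hat = estimate_k(scan.silhouettes)
                labels = labels_by_k[scan.k_hat]
                frames_metrics = []
                for sid, day, kept_idx, run_ids, start, end in spans:
                    seq = StateSequence(
                        subject_id=sid, day=day, labels=labels[start:end],
                        kept_frame_indices=kept_idx, run_ids=run_ids,
                        source=(p, split_id),
                    )
                    frames_metrics.append(
                        compute_metrics(seq, n_states=scan.k_hat,
                                        break_at_runs=break_at_runs)
                    )
                metrics = pd.concat(frames_metrics, ignore_index=True)
                metrics["permutation"] = p
                metrics["split"] = split_id
                metrics["k_hat"] = scan.k_hat
                splits.append(SplitResult(subject_ids=members, scan=scan,
                                          metrics=metrics))
            records.append(PermutationRecord(p, splits, excluded_subject=excluded))
        except Exception as exc:  # recorded, never silently dropped
            logger.exception("permutation %d failed", p)
            records.append(PermutationRecord(p, [], error=str(exc)))
    _ = root  # base SeedSequence kept for provenance symmetry
    return PermutationLedger(records=records, k_range=tuple(sorted(k_range)),
                             base_seed=base_seed)
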