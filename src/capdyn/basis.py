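"""Basis CAPs: aggregation across permutations, matching, and Δ occurrence.

Centroids from every permutation whose split yielded the same k̂ are pooled
and hierarchically clustered (ward/Euclidean) into k̂ clusters; the
parcel-wise mean of each cluster, z-scored across parcels, is a basis CAP.
Estimated CAPs are labeled against a basis set by one-to-one greedy Pearson
matching (globally largest unused correlation first).  The per-subject
Δ-occurrence statistic counts, per split, the permutations yielding a 5-CAP
versus a 4-CAP solution among those containing the subject; the split-mean
difference, z-scored across subjects, indexes a subject's propensity toward
the extra CAP.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import rankdata

from .cap_estimation import PermutationLedger

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class BasisCapSet:
    """z-scored permutation-average CAP patterns."""

    patterns: np.ndarray      # k x P, each row mean 0 / SD 1 across parcels
    labels: list[str]
    k: int
    n_contributing_permutations: int
    cluster_sizes: np.ndarray


def build_basis_set(
    ledger: PermutationLedger,
    k: int,
    split_id: int | None = None,
) -> BasisCapSet:
    """Aggregate all k̂ = ``k`` centroids in the ledger into k basis CAPs.

    ``split_id`` restricts to one split (None pools both).  Requires at
    least 2 qualifying permutation-splits.  Clusters capturing < 1% of
    members are flagged as unstable.
    """
    stacks, perm_ids = [], set()
    for perm_id, sid_, split in ledger.iter_splits():
        if split.k_hat != k:
            continue
        if split_id is not None and sid_ != split_id:
            continue
        stacks.append(split.capset.centroids)
        perm_ids.add(perm_id)
    if len(stacks) < 2:
        raise ValueError(
            f"only {len(stacks)} permutation-splits yielded k̂={k}; need >= 2"
        )
    X = np.vstack(stacks)                       # (k*h) x P
    Z = linkage(X, method="ward", metric="euclidean")
    assign = fcluster(Z, t=k, criterion="maxclust")
    patterns, sizes = [], []
    for c in range(1, k + 1):
        members = X[assign == c]
        sizes.append(members.shape[0])
        mean = members.mean(axis=0)
        patterns.append((mean - mean.mean()) / mean.std())
    sizes = np.asarray(sizes)
    if (sizes < max(1, 0.01 * X.shape[0])).any():
        warnings.warn(
            f"unstable basis set for k={k}: cluster sizes {sizes.tolist()}",
            stacklevel=2,
        )
    # deterministic ordering: descending cluster size, then first-parcel value
    order = np.lexsort((-np.abs([p[0] for p in patterns]), -sizes))
    patterns = [patterns[i] for i in order]
    sizes = sizes[order]
    return BasisCapSet(
        patterns=np.vstack(patterns),
        labels=[f"BC{i + 1}" for i in range(k)],
        k=k,
        n_contributing_permutations=len(perm_ids),
        cluster_sizes=sizes,
    )


def label_basis_set(basis: BasisCapSet) -> BasisCapSet:
    """Assign the conventional I+/I-/II+/II-/III names.

    Anti-correlated pattern pairs are paired greedily by most-negative
    spatial correlation and named I, II, ... in pairing order; within a
    pair, '+' goes to the member whose largest-|z| parcel is positive.
    Leftover unpaired patterns (e.g. the 5th CAP) are named III, IV, ...
    The pattern order is unchanged; only labels are rewritten.
    """
    P = basis.patterns
    k = basis.k
    r = np.corrcoef(P)
    unused = set(range(k))
    pairs = []
    while len(unused) >= 2:
        best = None
        for i in sorted(unused):
            for j in sorted(unused):
                if i < j and (best is None or r[i, j] < best[0]):
                    best = (r[i, j], i, j)
        if best is None or best[0] > -0.5:   # no convincing anti-pair left
            break
        _, i, j = best
        pairs.append((i, j))
        unused -= {i, j}
    romans = ["I", "II", "IV", "V"]
    labels = [""] * k
    for idx, (i, j) in enumerate(pairs):
        roman = romans[idx] if idx < len(romans) else f"P{idx + 1}"
        pi = i if P[i, np.argmax(np.abs(P[i]))] > 0 else j
        ni = j if pi == i else i
        labels[pi] = f"{roman}+"
        labels[ni] = f"{roman}-"
    extra_names = iter(["III"] + [f"X{n}" for n in range(2, 10)])
    for i in sorted(unused):
        labels[i] = next(extra_names)
    return dataclasses.replace(basis, labels=labels)


def match_caps(
    estimated: np.ndarray,
    basis: BasisCapSet,
    method: str = "pearson",
) -> tuple[dict[int, int], np.ndarray, np.ndarray]:
    """One-to-one greedy matching of estimated CAPs to basis CAPs.

    Computes the full estimated x basis correlation matrix over parcels
    (Pearson by default; ``method='spearman'`` rank-transforms first), then
    repeatedly takes the globally largest unused (i, j) pair.  Ties at
    machine precision break toward the lower basis index.  Returns
    ``(labeling, corr_matrix, best_r)`` where labeling maps estimated index
    -> basis index and best_r is each estimated CAP's maximum correlation.
    """
    E = np.asarray(estimated, dtype=float)
    if E.shape[0] > basis.k:
        raise ValueError(
            f"{E.shape[0]} estimated CAPs cannot one-to-one match {basis.k} basis CAPs"
        )
    B = basis.patterns
    if method == "spearman":
        E = np.apply_along_axis(rankdata, 1, E)
        B = np.apply_along_axis(rankdata, 1, B)
    elif method != "pearson":
        raise ValueError(f"unknown correlation method {method!r}")
    Ec = E - E.mean(axis=1, keepdims=True)
    Bc = B - B.mean(axis=1, keepdims=True)
    R = (Ec @ Bc.T) / (
        np.linalg.norm(Ec, axis=1)[:, None] * np.linalg.norm(Bc, axis=1)[None, :]
    )
    labeling: dict[int, int] = {}
    used_e: set[int] = set()
    used_b: set[int] = set()
    work = R.copy()
    for _ in range(E.shape[0]):
        masked = work.copy()
        masked[list(used_e), :] = -np.inf
        masked[:, list(used_b)] = -np.inf
        best = masked.max()
        cand = np.argwhere(masked == best)
        if cand.shape[0] > 1:
            logger.info("greedy matching tie at r=%.12g; lower basis index wins", best)
            cand = cand[np.lexsort((cand[:, 0], cand[:, 1]))]
        i, j = int(cand[0, 0]), int(cand[0, 1])
        labeling[i] = j
        used_e.add(i)
        used_b.add(j)
    best_r = R.max(axis=1)
    return labeling, R, best_r


def exhaustive_match(estimated: np.ndarray, basis: BasisCapSet) -> dict[int, int]:
    """Brute-force assignment maximizing total correlation (small k only)."""
    from itertools import permutations

    E = np.asarray(estimated, dtype=float)
    Ec = E - E.mean(axis=1, keepdims=True)
    Bc = basis.patterns - basis.patterns.mean(axis=1, keepdims=True)
    R = (Ec @ Bc.T) / (
        np.linalg.norm(Ec, axis=1)[:, None] * np.linalg.norm(Bc, axis=1)[None, :]
    )
    best, best_total = None, -np.inf
    for perm in permutations(range(basis.k), E.shape[0]):
        total = sum(R[i, j] for i, j in enumerate(perm))
        if total > best_total:
            best_total, best = total, perm
    return {i: j for i, j in enumerate(best)}


def matched_metrics_table(
    ledger: PermutationLedger,
    basis: BasisCapSet,
    method: str = "pearson",
) -> pd.DataFrame:
    """Tidy per-permutation temporal metrics with basis-matched CAP labels.

    Every split whose k̂ admits a one-to-one match into the basis set
    (k̂ <= basis.k) contributes rows; cluster indices are replaced by the
    matched basis labels.  The matching is also stored back onto each
    SplitResult.
    """
    frames = []
    for _, _, split in ledger.iter_splits():
        if split.k_hat > basis.k:
            continue
        labeling, _, _ = match_caps(split.capset.centroids, basis, method=method)
        split.matched_labels = {e: basis.labels[b] for e, b in labeling.items()}
        m = split.metrics.copy()
        m["cap_label"] = m["state"].map(split.matched_labels)
        frames.append(m.drop(columns=["state"]))
    if not frames:
        raise ValueError("no split in the ledger is matchable to this basis set")
    return pd.concat(frames, ignore_index=True)


def occurrence_stats(
    ledger: PermutationLedger,
    subjects: list[str] | None = None,
    k_with: int = 5,
    k_without: int = 4,
) -> pd.DataFrame:
    """Per-subject Δ occurrence = occ(k=5) − occ(k=4), split-averaged, z-scored.

    Counts, per subject per split, the permutations in which the subject was
    a member of that split and the split's k̂ equalled ``k_with`` resp.
    ``k_without``; other k̂ values count toward neither.  The per-split
    differences are averaged within subject and z-scored across subjects.
    """
    counts: dict[str, np.ndarray] = {}
    for _, split_id, split in ledger.iter_splits():
        for sid in split.subject_ids:
            c = counts.setdefault(sid, np.zeros(4))  # occ4_s1 occ5_s1 occ4_s2 occ5_s2
            if split.k_hat == k_without:
                c[2 * split_id] += 1
            elif split.k_hat == k_with:
                c[2 * split_id + 1] += 1
    if subjects is None:
        subjects = sorted(counts)
    missing = [s for s in subjects if s not in counts]
    if missing:
        warnings.warn(f"subjects never sampled, excluded: {missing}", stacklevel=2)
        subjects = [s for s in subjects if s in counts]
    rows = []
    for sid in subjects:
        occ4_s1, occ5_s1, occ4_s2, occ5_s2 = counts[sid]
        d1, d2 = occ5_s1 - occ4_s1, occ5_s2 - occ4_s2
        rows.append({
            "subject_id": sid,
            "occ4_s1": occ4_s1, "occ5_s1": occ5_s1,
            "occ4_s2": occ4_s2, "occ5_s2": occ5_s2,
            "delta_s1": d1, "delta_s2": d2,
            "delta_mean": 0.5 * (d1 + d2),
        })
    out = pd.DataFrame(rows)
    sd = out["delta_mean"].std(ddof=0)
    if sd == 0:
        warnings.warn("Δ occurrence has zero variance; delta_z set to 0", stacklevel=2)
        out["delta_z"] = 0.0
    else:
        out["delta_z"] = (out["delta_mean"] - out["delta_mean"].mean()) / sd
    return out


def basis_similarity(a: BasisCapSet, b: BasisCapSet) -> pd.DataFrame:
    """Pearson correlation matrix between two basis sets (rows of a x rows of b)."""
    Ac = a.patterns - a.patterns.mean(axis=1, keepdims=True)
    Bc = b.patterns - b.patterns.mean(axis=1, keepdims=True)
    R = (Ac @ Bc.T) / (
        np.linalg.norm(Ac, axis=1)[:, None] * np.linalg.norm(Bc, axis=1)[None, :]
    )
    return pd.DataFrame(R, index=a.labels, columns=b.labels)
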