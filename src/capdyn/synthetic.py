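"""Synthetic cohorts with planted co-activation-pattern (CAP) structure.

The generator emulates the statistical structure the CAP pipeline assumes:

* fixed spatial patterns per state, built as anti-correlated sign-flipped
  pairs (I+/I-, II+/II-) plus one optional extra state (III) carried only by
  a subgroup of subjects;
* Markov-switching state sequences whose self-transition probabilities vary
  between subjects (trait variance) and between days (state variance), both
  implemented as Gaussian perturbations on the self-transition logit;
* i.i.d. Gaussian parcel noise around ``snr x pattern`` at every frame;
* a framewise-displacement series with a low baseline plus randomly placed
  motion spikes exceeding the scrub threshold;
* behavioral variables generated as linear combinations of latent neural
  factors (planted occupancy and persistence contrasts) plus noise, with a
  subset stored as positive reaction-time-like variables (exercising the
  1/RT transform) and age/sex covariates.

Runs are emitted already dummy-trimmed: downstream preprocessing of synthetic
cohorts should use ``n_dummy=0`` so ground-truth state sequences stay aligned
frame-for-frame with the signal.

All randomness flows from a single master seed; identical configs produce
bitwise-identical cohorts.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .io_preprocess import ParcelTimeSeries

STATE_LABELS_4 = ["I+", "I-", "II+", "II-"]
EXTRA_STATE_LABEL = "III"


@dataclasses.dataclass
class SimConfig:
    """Generator settings; defaults define the package's reference conditions."""

    n_subjects: int = 20
    n_parcels: int = 64
    n_runs: int = 2          # runs per day; 2 days are always generated
    frames_per_run: int = 200
    tr: float = 0.72
    n_states: int = 4        # base states, built as sign-flipped pairs
    p_stay: float = 0.8      # baseline self-transition probability
    trait_sd: float | tuple = 0.5   # SD of subject effect on self-transition logit
    day_sd: float | tuple = 0.2     # SD of day effect on self-transition logit
    frac_subgroup_C: float = 0.3    # fraction of subjects carrying the extra state
    extra_state_occupancy: float = 0.03  # stationary mass of state III in carriers
    subgroup_b_shift: float = 0.75  # logit shift on CAP II states for subgroup B
    snr: float = 1.0         # pattern amplitude / noise SD
    fd_baseline: float = 0.08
    fd_baseline_sd: float = 0.03
    fd_spike_rate: float = 0.02     # per-frame spike probability
    fd_spike_magnitude: float = 1.0  # mm added during a spike
    n_behavior_variables: int = 40
    n_latent_factors: int = 2
    behavior_noise_sd: float = 1.0
    rt_fraction: float = 0.2        # fraction of variables stored as RT
    sex_effect: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_stay <= 1.0):
            raise ValueError("p_stay must be a probability")
        if not (0.0 <= self.frac_subgroup_C <= 1.0):
            raise ValueError("frac_subgroup_C must be a probability")
        if self.snr < 0:
            raise ValueError("snr must be >= 0")
        if self.n_behavior_variables < self.n_latent_factors:
            raise ValueError("need at least as many behavioral variables as factors")


@dataclasses.dataclass
class GroundTruth:
    """Everything the generator decided, for parameter-recovery tests."""

    patterns: np.ndarray                 # K_total x P, z-scaled
    state_labels: list[str]
    transition_matrices: dict            # (subject_id, day) -> K_total x K_total
    state_sequences: dict                # (subject_id, day) -> int labels per frame
    stationary: dict                     # (subject_id, day) -> stationary probs
    subgroup: dict                       # subject_id -> 'A' | 'B' | 'C'
    latent_factors: pd.DataFrame         # subjects x factors
    behavioral_loadings: np.ndarray      # factors x variables
    seed: int


def _zscale(v: np.ndarray) -> np.ndarray:
    return (v - v.mean()) / v.std()


def make_patterns(n_states: int, n_parcels: int, rng: np.random.Generator,
                  extra_state: bool = False) -> tuple[np.ndarray, list[str]]:
    """Spatial patterns: sign-flipped pairs, optionally plus one extra state."""
    n_pairs, odd = divmod(n_states, 2)
    rows, labels = [], []
    for i in range(n_pairs):
        base = _zscale(rng.standard_normal(n_parcels))
        roman = "I" * (i + 1) if i < 3 else f"P{i + 1}"
        rows += [base, -base]
        labels += [f"{roman}+", f"{roman}-"]
    if odd:
        rows.append(_zscale(rng.standard_normal(n_parcels)))
        labels.append(f"S{n_states}")
    if extra_state:
        rows.append(_zscale(rng.standard_normal(n_parcels)))
        labels.append(EXTRA_STATE_LABEL)
    return np.vstack(rows), labels


def _sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-x))


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


def build_transition_matrix(
    self_logits: np.ndarray,
    allowed: np.ndarray,
    n_total: int,
    extra_idx: int | None = None,
    extra_entry: float = 0.0,
) -> np.ndarray:
    """Row-stochastic matrix over ``n_total`` states restricted to ``allowed``.

    When ``extra_idx`` names a rare extra state among the allowed states,
    every other state enters it with absolute probability ``extra_entry``
    (instead of an equal share of the off-diagonal mass), which pins its
    stationary occupancy well below the others'.  Rows of disallowed states
    (unreachable; zero stationary mass) are set to the uniform distribution
    over allowed states so every row is stochastic.
    """
    T = np.zeros((n_total, n_total))
    allowed = np.asarray(allowed)
    n_allowed = len(allowed)
    main = np.array([s for s in allowed
                     if extra_idx is None or s != extra_idx])
    for idx, s in enumerate(allowed):
        p_self = float(_sigmoid(self_logits[idx]))
        if n_allowed == 1:
            T[s, s] = 1.0
            continue
        others = allowed[allowed != s]
        if extra_idx is not None and s != extra_idx:
            off = 1.0 - p_self
            entry = min(extra_entry, 0.9 * off)
            main_others = main[main != s]
            T[s, extra_idx] = entry
            T[s, main_others] = (off - entry) / len(main_others)
        else:
            T[s, others] = (1.0 - p_self) / len(others)
        T[s, s] = p_self
    for s in range(n_total):
        if s not in allowed:
            T[s, allowed] = 1.0 / n_allowed
    return T


def extra_entry_for_occupancy(occupancy: float, p_stay_extra: float) -> float:
    """Entry probability giving the extra state a target stationary mass.

    From the one-step balance pi = pi * p_stay + (1 - pi) * entry:
    entry = pi (1 - p_stay) / (1 - pi).
    """
    if not (0.0 < occupancy < 1.0):
        raise ValueError("occupancy must be in (0, 1)")
    return occupancy * (1.0 - p_stay_extra) / (1.0 - occupancy)


def stationary_distribution(T: np.ndarray) -> np.ndarray:
    """Left eigenvector of the transition matrix for eigenvalue 1, normalized."""
    w, v = np.linalg.eig(T.T)
    i = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, i])
    pi *= np.sign(pi[int(np.argmax(np.abs(pi)))])  # eigenvector sign is arbitrary
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def sample_state_sequence(transition: np.ndarray, n_frames: int,
                          rng: np.random.Generator | int) -> np.ndarray:
    """Markov chain labels; first state drawn from the stationary distribution."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    T = np.asarray(transition, dtype=float)
    if T.ndim != 2 or T.shape[0] != T.shape[1]:
        raise ValueError("transition must be square")
    if not np.allclose(T.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("transition rows must sum to 1")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    K = T.shape[0]
    pi = stationary_distribution(T)
    labels = np.empty(n_frames, dtype=np.int64)
    labels[0] = rng.choice(K, p=pi)
    # vectorized inverse-CDF stepping
    cdf = np.cumsum(T, axis=1)
    u = rng.random(n_frames - 1)
    for t in range(1, n_frames):
        labels[t] = int(np.searchsorted(cdf[labels[t - 1]], u[t - 1], side="right"))
    return labels


def render_frames(states: np.ndarray, patterns: np.ndarray, snr: float,
                  rng: np.random.Generator | int, noise_sd: float = 1.0) -> np.ndarray:
    """Frame t = snr * pattern(state_t) + Gaussian(0, noise_sd) per parcel."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    states = np.asarray(states)
    if states.min() < 0 or states.max() >= patterns.shape[0]:
        raise ValueError("state label outside pattern rows")
    signal = snr * patterns[states]
    if noise_sd == 0:
        return signal.copy()
    return signal + noise_sd * rng.standard_normal(signal.shape)


def _fd_series(n_frames: int, cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    fd = np.abs(cfg.fd_baseline + cfg.fd_baseline_sd * rng.standard_normal(n_frames))
    spikes = rng.random(n_frames) < cfg.fd_spike_rate
    fd[spikes] += cfg.fd_spike_magnitude
    return fd


def generate_behavior(ground_truth: GroundTruth, config: SimConfig,
                      rng: np.random.Generator | int,
                      subjects: pd.DataFrame | None = None
                      ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Behavioral table from latent neural factors plus noise.

    Returns ``(values, metadata, covariates)``: a subjects x variables table,
    per-variable metadata (domain, is_reaction_time), and an age/sex table.
    RT-flagged variables are stored as ``1 / (shift + y)`` with a per-variable
    shift keeping them strictly positive, so the pipeline's reciprocal
    transform recovers the underlying linear variable exactly.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    factors = ground_truth.latent_factors.to_numpy()
    n_sub, n_fac = factors.shape
    n_var = config.n_behavior_variables
    if n_var < n_fac:
        raise ValueError("fewer behavioral variables than latent factors")
    loadings = ground_truth.behavioral_loadings
    y = factors @ loadings + config.behavior_noise_sd * rng.standard_normal((n_sub, n_var))

    if subjects is None:
        subjects = pd.DataFrame({
            "subject_id": ground_truth.latent_factors.index,
            "age": rng.integers(22, 38, size=n_sub),
            "sex": rng.integers(0, 2, size=n_sub),
        })
    sex = subjects["sex"].to_numpy(dtype=float)
    sex_cols = rng.random(n_var) < 0.1
    y[:, sex_cols] += config.sex_effect * sex[:, None]

    n_rt = int(round(config.rt_fraction * n_var))
    is_rt = np.zeros(n_var, dtype=bool)
    is_rt[:n_rt] = True
    values = y.copy()
    for j in np.flatnonzero(is_rt):
        shift = 0.5 - y[:, j].min()
        values[:, j] = 1.0 / (shift + y[:, j])

    cols = [f"beh{j:03d}" for j in range(n_var)]
    table = pd.DataFrame(values, columns=cols,
                         index=ground_truth.latent_factors.index)
    meta = pd.DataFrame({
        "variable": cols,
        "domain": [f"domain{j % 5}" for j in range(n_var)],
        "is_reaction_time": is_rt,
    })
    return table, meta, subjects


def generate_cohort(config: SimConfig
                    ) -> tuple[dict, GroundTruth, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Full synthetic cohort.

    Returns ``(cohort, ground_truth, behavior, behavior_meta, subjects)``;
    ``cohort`` maps (subject_id, day) to a ParcelTimeSeries.
    """
    rng = np.random.default_rng(config.seed)
    has_extra = config.frac_subgroup_C > 0
    patterns, labels = make_patterns(config.n_states, config.n_parcels, rng,
                                     extra_state=has_extra)
    n_total = patterns.shape[0]
    subject_ids = [f"s{i:03d}" for i in range(config.n_subjects)]

    # subgroup assignment: last frac_C of a shuffled order is C; rest split A/B
    order = rng.permutation(config.n_subjects)
    n_c = int(round(config.frac_subgroup_C * config.n_subjects))
    subgroup = {}
    non_c = [subject_ids[i] for i in order[: config.n_subjects - n_c]]
    for j, sid in enumerate(non_c):
        subgroup[sid] = "A" if j < (len(non_c) + 1) // 2 else "B"
    for i in order[config.n_subjects - n_c:]:
        subgroup[subject_ids[i]] = "C"

    trait_sd = np.broadcast_to(np.asarray(config.trait_sd, dtype=float), (n_total,))
    day_sd = np.broadcast_to(np.asarray(config.day_sd, dtype=float), (n_total,))
    base_logit = _logit(config.p_stay)

    cohort: dict[tuple[str, int], ParcelTimeSeries] = {}
    transition_matrices, state_sequences, stationary = {}, {}, {}
    persistence = np.zeros(config.n_subjects)   # subject mean self-logit deviation
    fo_state0 = np.zeros(config.n_subjects)     # stationary mass of state I+

    frames_per_day = config.n_runs * config.frames_per_run
    for i, sid in enumerate(subject_ids):
        allowed = np.arange(n_total) if subgroup[sid] == "C" else np.arange(
            min(config.n_states, n_total))
        subj_eff = rng.normal(0.0, trait_sd)
        if subgroup[sid] == "B":
            # subgroup B is shifted on the CAP II pair, giving A/B structure
            for k, lab in enumerate(labels):
                if lab.startswith("II"):
                    subj_eff[k] += config.subgroup_b_shift
        persistence[i] = subj_eff[allowed].mean()
        for day in (1, 2):
            day_eff = rng.normal(0.0, day_sd)
            logits = base_logit + subj_eff + day_eff
            if subgroup[sid] == "C":
                extra_idx = n_total - 1
                entry = extra_entry_for_occupancy(
                    config.extra_state_occupancy,
                    float(_sigmoid(logits[extra_idx])))
                T = build_transition_matrix(logits[allowed], allowed, n_total,
                                            extra_idx=extra_idx,
                                            extra_entry=entry)
            else:
                T = build_transition_matrix(logits[allowed], allowed, n_total)
            transition_matrices[(sid, day)] = T
            pi = stationary_distribution(T)
            stationary[(sid, day)] = pi
            if day == 1:
                fo_state0[i] = pi[0]
            run_labels = [
                sample_state_sequence(T, config.frames_per_run, rng)
                for _ in range(config.n_runs)
            ]
            seq = np.concatenate(run_labels)
            state_sequences[(sid, day)] = seq
            data = render_frames(seq, patterns, config.snr, rng)
            boundaries = [
                (r * config.frames_per_run, (r + 1) * config.frames_per_run)
                for r in range(config.n_runs)
            ]
            cohort[(sid, day)] = ParcelTimeSeries(
                subject_id=sid, day=day, data=data,
                run_boundaries=boundaries,
                fd=_fd_series(frames_per_day, config, rng),
                tr=config.tr,
            )

    # latent neural factors: planted occupancy contrast and persistence trait
    factor_cols = {"fo_I+": _zscale(fo_state0), "persistence": _zscale(persistence)}
    for extra in range(config.n_latent_factors - 2):
        factor_cols[f"noise_factor{extra}"] = rng.standard_normal(config.n_subjects)
    factors = pd.DataFrame(factor_cols, index=pd.Index(subject_ids, name="subject_id"))
    factors = factors.iloc[:, : config.n_latent_factors]
    loadings = rng.standard_normal((config.n_latent_factors, config.n_behavior_variables))

    gt = GroundTruth(
        patterns=patterns, state_labels=labels,
        transition_matrices=transition_matrices,
        state_sequences=state_sequences, stationary=stationary,
        subgroup=subgroup, latent_factors=factors,
        behavioral_loadings=loadings, seed=config.seed,
    )
    subjects = pd.DataFrame({
        "subject_id": subject_ids,
        "age": rng.integers(22, 38, size=config.n_subjects),
        "sex": rng.integers(0, 2, size=config.n_subjects),
        "subgroup": [subgroup[s] for s in subject_ids],
    })
    behavior, meta, subjects = generate_behavior(gt, config, rng, subjects)
    return cohort, gt, behavior, meta, subjects


def save_ground_truth(gt: GroundTruth, path: str | Path) -> None:
    """JSON-serialize ground truth (arrays as nested lists)."""
    payload = {
        "patterns": gt.patterns.tolist(),
        "state_labels": gt.state_labels,
        "subgroup": gt.subgroup,
        "seed": gt.seed,
        "stationary": {f"{s}|{d}": pi.tolist() for (s, d), pi in gt.stationary.items()},
        "transition_matrices": {
            f"{s}|{d}": T.tolist() for (s, d), T in gt.transition_matrices.items()
        },
    }
    Path(path).write_text(json.dumps(payload))
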