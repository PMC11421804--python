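"""Per-subject neural state-trait feature space.

Each subject is summarized by 3 temporal measures (FO, mean DT, var DT) x
k CAPs x 2 days (30 features for the canonical 5-CAP set).  Subgroups are
found by ward/Euclidean agglomerative clustering with flat clusters cut at a
fraction (default 70%) of the final-merge height, and the principal geometry
of the feature space comes from PCA with per-day loading profiles and a
between-day loading correlation per component (a strongly negative value
flags a day-flip component).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import pearsonr

from .temporal import METRIC_NAMES

DEFAULT_DENDROGRAM_CUT = 0.70


@dataclasses.dataclass
class FeatureMatrix:
    """Subjects x (metric x CAP x day) matrix with a fixed column schema."""

    values: np.ndarray
    subject_ids: list[str]
    columns: list[str]           # "<metric>_<cap>_d<day>"
    standardized: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.subject_ids, columns=self.columns)


@dataclasses.dataclass
class PcaModel:
    loadings: np.ndarray          # features x components, orthonormal columns
    scores: np.ndarray            # subjects x components
    variance_explained: np.ndarray  # percent, non-increasing
    columns: list[str]


def build_feature_matrix(
    metrics: pd.DataFrame,
    cap_labels: list[str] | None = None,
    standardize: bool = True,
) -> FeatureMatrix:
    """Assemble the per-subject feature matrix from permutation-averaged metrics.

    Column order is metric-major: (fo, mean_dt, var_dt) x CAP x day.  CAPs a
    subject never exhibits contribute zeros (the include-as-zeros averaging
    convention).  Every subject must have both days.  Columns are z-scored
    across subjects by default (FO is a fraction, DT measures are in TR;
    the units are incommensurate).
    """
    if cap_labels is None:
        cap_labels = sorted(metrics["cap_label"].unique())
    days = sorted(metrics["day"].unique())
    if set(days) != {1, 2}:
        raise ValueError(f"expected days {{1, 2}}, got {days}")
    have_days = metrics.groupby("subject_id")["day"].nunique()
    incomplete = have_days[have_days < 2].index.tolist()
    if incomplete:
        raise ValueError(f"subjects missing a day: {incomplete}")
    subject_ids = sorted(metrics["subject_id"].unique())

    columns, blocks = [], []
    for metric in METRIC_NAMES:
        for cap in cap_labels:
            for day in (1, 2):
                columns.append(f"{metric}_{cap}_d{day}")
                cell = (
                    metrics[(metrics["cap_label"] == cap) & (metrics["day"] == day)]
                    .set_index("subject_id")[metric]
                    .reindex(subject_ids)
                    .fillna(0.0)
                )
                blocks.append(cell.to_numpy())
    values = np.column_stack(blocks)
    if standardize:
        sd = values.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0            # all-zero columns (absent CAP) stay zero
        values = (values - values.mean(axis=0)) / sd
    return FeatureMatrix(values=values, subject_ids=subject_ids,
                         columns=columns, standardized=standardize)


def cluster_subgroups(
    features: FeatureMatrix,
    cut_fraction: float = DEFAULT_DENDROGRAM_CUT,
) -> tuple[pd.Series, np.ndarray]:
    """Ward/Euclidean subgroups at a fractional dendrogram cut.

    Flat clusters are formed by cutting the dendrogram at
    ``cut_fraction x (height of the final merge)``.  Labels are letters
    ordered by descending cluster size.  Returns (labels, linkage matrix).
    """
    X = features.values
    if X.shape[0] < 3:
        raise ValueError("need >= 3 subjects to cluster")
    if np.allclose(X, X[0]):
        warnings.warn("all subjects identical; single cluster", stacklevel=2)
        return (pd.Series(["A"] * X.shape[0], index=features.subject_ids,
                          name="subgroup"), linkage(X, method="ward"))
    Z = linkage(X, method="ward", metric="euclidean")
    cut = cut_fraction * Z[-1, 2]
    raw = fcluster(Z, t=cut, criterion="distance")
    sizes = pd.Series(raw).value_counts()
    letters = {c: chr(ord("A") + i) for i, c in enumerate(sizes.index)}
    labels = pd.Series([letters[c] for c in raw], index=features.subject_ids,
                       name="subgroup")
    return labels, Z


def neural_pca(
    features: FeatureMatrix,
    n_components: int = 3,
) -> tuple[PcaModel, pd.DataFrame]:
    """PCA of the feature matrix plus per-day loading reliability.

    Components are extracted from the column-centered matrix by SVD; the
    sign convention (largest-|loading| element positive) makes output
    deterministic.  For each component, the loadings are split into day-1
    and day-2 halves (matched feature-by-feature) and their Pearson r is
    reported — a strongly negative r marks a day-flip component.
    """
    X = features.values
    n_sub, n_feat = X.shape
    if n_components >= n_sub:
        raise ValueError("need more subjects than requested components")
    Xc = X - X.mean(axis=0)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int((S > S[0] * 1e-10).sum()) if S.size else 0
    if n_components > rank:
        warnings.warn(
            f"requested {n_components} components but rank is {rank}; "
            "components beyond rank are noise", stacklevel=2,
        )
    load = Vt[:n_components].T
    scores = U[:, :n_components] * S[:n_components]
    # deterministic sign: dominant loading positive
    for c in range(load.shape[1]):
        j = int(np.argmax(np.abs(load[:, c])))
        if load[j, c] < 0:
            load[:, c] *= -1
            scores[:, c] *= -1
    var_exp = 100.0 * (S**2) / (S**2).sum()
    model = PcaModel(loadings=load, scores=scores,
                     variance_explained=var_exp[:n_components],
                     columns=features.columns)

    d1_idx = [i for i, c in enumerate(features.columns) if c.endswith("_d1")]
    d2_idx = [i for i, c in enumerate(features.columns) if c.endswith("_d2")]
    # align day-2 features to their day-1 counterparts
    base = {features.columns[i][:-3]: i for i in d1_idx}
    pairs = [(base[features.columns[i][:-3]], i) for i in d2_idx
             if features.columns[i][:-3] in base]
    rows = []
    for c in range(n_components):
        v1 = load[[p[0] for p in pairs], c]
        v2 = load[[p[1] for p in pairs], c]
        if np.std(v1) == 0 or np.std(v2) == 0:
            r, p = np.nan, np.nan
        else:
            r, p = pearsonr(v1, v2)
        rows.append({"component": c + 1, "between_day_loading_r": r, "p": p})
    return model, pd.DataFrame(rows)
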