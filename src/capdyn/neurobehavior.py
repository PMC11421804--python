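"""Behavioral PCA and the neuro-behavioral association model.

Behavioral tables are subjects x variables DataFrames with a metadata
sidecar (variable, domain, is_reaction_time).  Preparation converts
reaction-time variables to 1/RT and standardizes every column.  The
significance of behavioral principal components is assessed against a
permutation null built by independently shuffling subject order within each
variable — destroying inter-variable correlation while preserving marginal
distributions — and component reproducibility by split-half PCA geometry
correlations.  The association model is an ordinary least-squares fit
(behavioral PC ~ neural PC 1..3 + age + sex) with the coefficient of
partial determination per predictor, cross-validated by training on split 1
and predicting split 2 across permutations.
"""

from __future__ import annotations

import dataclasses
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

N_NEURAL_COMPONENTS = 3


def _pca(X: np.ndarray, n_components: int | None = None):
    """Centered-SVD PCA: (loadings, scores, variance-explained fraction)."""
    Xc = X - X.mean(axis=0)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    if n_components is None:
        n_components = min(Xc.shape) - 1
    load = Vt[:n_components].T
    scores = U[:, :n_components] * S[:n_components]
    for c in range(load.shape[1]):   # dominant-loading-positive sign convention
        j = int(np.argmax(np.abs(load[:, c])))
        if load[j, c] < 0:
            load[:, c] *= -1
            scores[:, c] *= -1
    var_frac = (S**2) / (S**2).sum()
    return load, scores, var_frac[:n_components]


def prepare_behavior(table: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Reciprocal-transform RT variables and standardize every column.

    RT-flagged columns (``meta.is_reaction_time``) must be strictly positive
    and are replaced by their reciprocals before all columns are centered to
    mean 0 and scaled to SD 1.  A provenance flag in ``DataFrame.attrs``
    guards against double preparation.
    """
    if table.attrs.get("capdyn_prepared"):
        raise ValueError("behavioral table is already prepared; refusing to re-transform")
    out = table.astype(float).copy()
    rt_vars = meta.loc[meta["is_reaction_time"].astype(bool), "variable"]
    for var in rt_vars:
        col = out[var]
        bad = col[col <= 0]
        if not bad.empty:
            raise ValueError(
                f"non-positive RT value in variable {var!r} "
                f"for subject {bad.index[0]!r}"
            )
        out[var] = 1.0 / col
    sd = out.std(ddof=0)
    constant = sd[sd == 0].index.tolist()
    if constant:
        raise ValueError(f"constant behavioral columns after transform: {constant}")
    out = (out - out.mean()) / sd
    out.attrs["capdyn_prepared"] = True
    return out


def pca_permutation_test(
    table: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    n_components: int | None = None,
) -> dict:
    """Component significance against a shuffled-subject null.

    For each of ``n_perm`` draws, every variable's subject order is permuted
    independently and the PCA re-run; a component's p-value is the add-one
    fraction of null variance-explained values at its rank that reach the
    observed value.  Returns loadings, scores, variance explained (%),
    p-values, and the indices of significant components.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100 for a meaningful null")
    X = table.to_numpy(dtype=float)
    n_sub, n_var = X.shape
    load, scores, var_frac = _pca(X, n_components)
    n_comp = var_frac.shape[0]
    rng = np.random.default_rng(seed)
    exceed = np.zeros(n_comp)
    for _ in range(n_perm):
        Xp = np.empty_like(X)
        for j in range(n_var):
            Xp[:, j] = X[rng.permutation(n_sub), j]
        _, _, null_frac = _pca(Xp, n_comp)
        exceed += null_frac >= var_frac
    p = (1.0 + exceed) / (1.0 + n_perm)
    if alpha < 1.0 / (1.0 + n_perm):
        raise ValueError(f"n_perm={n_perm} cannot resolve alpha={alpha}")
    return {
        "loadings": load,
        "scores": pd.DataFrame(scores, index=table.index,
                               columns=[f"PC{c+1}" for c in range(n_comp)]),
        "variance_explained": 100.0 * var_frac,
        "p_values": p,
        "significant": np.flatnonzero(p < alpha),
        "n_significant": int((p < alpha).sum()),
    }


def splithalf_reproducibility(
    table: pd.DataFrame,
    n_perm: int = 100,
    n_components: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Split-half similarity of PC geometry per component rank.

    Per permutation, subjects are split into random halves, PCA is fit in
    each, and the |Pearson r| between same-rank loading vectors recorded
    (absolute value absorbs the sign indeterminacy of PCA).  Returns the
    per-component similarity distribution summarized as mean and SD.
    """
    X = table.to_numpy(dtype=float)
    n_sub = X.shape[0]
    if n_sub < 8:
        raise ValueError("need >= 8 subjects for split-half PCA")
    max_rank = n_sub // 2 - 1
    if n_components > max_rank:
        raise ValueError(
            f"component rank {n_components} exceeds half-sample rank {max_rank}"
        )
    rng = np.random.default_rng(seed)
    sims = np.empty((n_perm, n_components))
    for p in range(n_perm):
        perm = rng.permutation(n_sub)
        half = n_sub // 2
        l1, _, _ = _pca(X[perm[:half]], n_components)
        l2, _, _ = _pca(X[perm[half: 2 * half]], n_components)
        for c in range(n_components):
            sims[p, c] = abs(stats.pearsonr(l1[:, c], l2[:, c])[0])
    return pd.DataFrame({
        "component": np.arange(1, n_components + 1),
        "similarity_mean": sims.mean(axis=0),
        "similarity_sd": sims.std(axis=0, ddof=1),
    })


@dataclasses.dataclass
class AssociationReport:
    """OLS association of one behavioral component with neural components."""

    params: pd.DataFrame        # beta, SE, t, p, partial R2 per predictor
    r_squared: float
    adj_r_squared: float
    f_stat: float
    f_pvalue: float
    df_model: int
    df_resid: int
    n: int


def fit_association(
    behavioral_scores: pd.Series,
    neural_scores: pd.DataFrame,
    covariates: pd.DataFrame,
    condition_threshold: float = 1e8,
) -> AssociationReport:
    """behavioral PC ~ neural PCs + age + sex, with partial R² per predictor.

    Partial R²_j = (SSE without predictor j − SSE full) / SSE without j.
    Complete cases only; requires at least 10 more subjects than predictors
    and a well-conditioned design matrix.
    """
    df = pd.concat([behavioral_scores.rename("y"), neural_scores, covariates],
                   axis=1, join="inner").dropna()
    predictors = [c for c in df.columns if c != "y"]
    n, p = df.shape[0], len(predictors)
    if n < p + 10:
        raise ValueError(f"{n} complete cases is too few for {p} predictors")
    X = sm.add_constant(df[predictors].astype(float))
    if np.linalg.cond(X.to_numpy()) > condition_threshold:
        raise ValueError("collinear predictors: design matrix is ill-conditioned")
    full = sm.OLS(df["y"].astype(float), X).fit()
    sse_full = float((full.resid ** 2).sum())
    rows = []
    for var in predictors:
        reduced_X = sm.add_constant(df[[c for c in predictors if c != var]].astype(float))
        reduced = sm.OLS(df["y"].astype(float), reduced_X).fit()
        sse_red = float((reduced.resid ** 2).sum())
        partial = 0.0 if sse_red == 0 else (sse_red - sse_full) / sse_red
        rows.append({
            "predictor": var,
            "beta": full.params[var],
            "se": full.bse[var],
            "t": full.tvalues[var],
            "p": full.pvalues[var],
            "partial_r2": partial,
        })
    return AssociationReport(
        params=pd.DataFrame(rows).set_index("predictor"),
        r_squared=float(full.rsquared),
        adj_r_squared=float(full.rsquared_adj),
        f_stat=float(full.fvalue),
        f_pvalue=float(full.f_pvalue),
        df_model=int(full.df_model),
        df_resid=int(full.df_resid),
        n=n,
    )


def crossval_predict(
    neural_features: pd.DataFrame,
    behavior: pd.DataFrame,
    covariates: pd.DataFrame,
    n_perm: int = 100,
    seed: int = 0,
    n_neural: int = N_NEURAL_COMPONENTS,
    behavioral_component: int = 1,
) -> dict:
    """Split-half cross-validated prediction of a behavioral component.

    Per permutation, subjects are split in half; neural and behavioral PCA
    and the OLS association model are all fit on split 1; split-2 subjects
    are projected onto the split-1 component spaces (split-1 centering) and
    their behavioral scores predicted.  Held-out R² = 1 − SSE/SST on
    split 2.  The null shuffles split-2 behavioral scores before scoring.
    Returns the held-out and null R² distributions.
    """
    common = neural_features.index.intersection(behavior.index).intersection(
        covariates.index)
    if len(common) < 20:
        raise ValueError("need >= 20 subjects for split-half cross-validation")
    Xn = neural_features.loc[common].to_numpy(dtype=float)
    Xb = behavior.loc[common].to_numpy(dtype=float)
    cov = covariates.loc[common].to_numpy(dtype=float)
    n_sub = len(common)
    rng = np.random.default_rng(seed)
    r2s, nulls = [], []
    n_skipped = 0
    for _ in range(n_perm):
        perm = rng.permutation(n_sub)
        half = n_sub // 2
        tr, te = perm[:half], perm[half: 2 * half]
        try:
            nl, _, _ = _pca(Xn[tr], n_neural)
            bl, _, _ = _pca(Xb[tr], behavioral_component)
            n_tr = (Xn[tr] - Xn[tr].mean(axis=0)) @ nl
            n_te = (Xn[te] - Xn[tr].mean(axis=0)) @ nl
            b_tr = ((Xb[tr] - Xb[tr].mean(axis=0)) @ bl)[:, behavioral_component - 1]
            b_te = ((Xb[te] - Xb[tr].mean(axis=0)) @ bl)[:, behavioral_component - 1]
            D_tr = sm.add_constant(np.column_stack([n_tr, cov[tr]]))
            D_te = np.column_stack([np.ones(len(te)), n_te, cov[te]])
            fit = sm.OLS(b_tr, D_tr).fit()
            pred = D_te @ fit.params
            sst = ((b_te - b_te.mean()) ** 2).sum()
            if sst == 0:
                raise np.linalg.LinAlgError("degenerate test-half variance")
            r2s.append(1.0 - ((b_te - pred) ** 2).sum() / sst)
            b_null = b_te[rng.permutation(len(b_te))]
            nulls.append(1.0 - ((b_null - pred) ** 2).sum() / sst)
        except np.linalg.LinAlgError:
            n_skipped += 1
    return {
        "heldout_r2": np.asarray(r2s),
        "null_r2": np.asarray(nulls),
        "n_skipped": n_skipped,
    }


def subgroup_ttests(
    scores: pd.DataFrame,
    subgroups: pd.Series,
    n_components_tested: int | None = None,
) -> pd.DataFrame:
    """Welch two-sample two-sided t-tests between subgroups per component.

    The Bonferroni family is (components tested) x (subgroup pairs); the
    family size is recorded in the output.  Each compared subgroup needs at
    least 3 members; degenerate (zero-variance) comparisons are flagged.
    """
    if n_components_tested is None:
        n_components_tested = scores.shape[1]
    comps = scores.columns[:n_components_tested]
    groups = sorted(subgroups.dropna().unique())
    pairs = list(combinations(groups, 2))
    family = len(pairs) * len(comps)
    rows = []
    for g1, g2 in pairs:
        i1 = subgroups[subgroups == g1].index.intersection(scores.index)
        i2 = subgroups[subgroups == g2].index.intersection(scores.index)
        if len(i1) < 3 or len(i2) < 3:
            raise ValueError(f"subgroup pair ({g1}, {g2}) has fewer than 3 members")
        for comp in comps:
            a, b = scores.loc[i1, comp], scores.loc[i2, comp]
            degenerate = a.std() == 0 and b.std() == 0
            if degenerate:
                t, p = np.nan, np.nan
            else:
                t, p = stats.ttest_ind(a, b, equal_var=False)
            rows.append({
                "group1": g1, "group2": g2, "component": comp,
                "t": t, "p": p,
                "p_bonferroni": min(1.0, p * family) if np.isfinite(p) else np.nan,
                "family_size": family,
                "degenerate": degenerate,
            })
    return pd.DataFrame(rows)
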