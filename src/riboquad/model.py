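"""Feature tables, clustering, PCA subsetting and RPFdist regression.

The modeling workflow mirrors a standard predictor-importance analysis of
upstream ribosome loading: build a per-transcript feature table spanning
abundance, length, base-composition, dsRNA-structure, quadruplex, uORF
and cis-element categories; cluster transcripts on (TE, dsRNA energy,
quadruplex energy) z-scores; subset quadruplex-marked transcripts in PCA
space; select predictors with an L1-penalized linear model; and fit a
gradient-boosted regression whose category-restricted variants quantify
how much RPFdist variance each feature family explains.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.ensemble import GradientBoostingRegressor
from sklearn.linear_model import LassoCV
from sklearn.model_selection import GridSearchCV, KFold, RepeatedKFold, cross_val_score

FEATURE_CATEGORIES = (
    "abundance", "length", "base_composition", "dsRNA", "rG4", "uORF", "other",
)

#: IUPAC stand-ins for known 5'-UTR cis-regulatory elements (approximate
#: consensus patterns; used as count features only)
DEFAULT_CIS_ELEMENTS = {
    "CERT": "CCYCCYCC",   # cytosine-enriched regulator of translation
    "PRTE": "YYYYYUYY",   # pyrimidine-rich translational element
    "TOP": "CYYYYY",      # 5' terminal oligopyrimidine-like
}

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "U": "U", "T": "U",
    "R": "[AG]", "Y": "[CU]", "S": "[CG]", "W": "[AU]",
    "K": "[GU]", "M": "[AC]", "B": "[CGU]", "D": "[AGU]",
    "H": "[ACU]", "V": "[ACG]", "N": "[ACGU]",
}


def iupac_regex(motif: str) -> re.Pattern:
    return re.compile("".join(_IUPAC[c] for c in motif.upper()))


def zscore_columns(df: pd.DataFrame) -> pd.DataFrame:
    """Center and scale every column; constant columns map to 0."""
    out = df.copy()
    for col in out.columns:
        v = out[col].to_numpy(dtype=float)
        sd = v.std(ddof=0)
        out[col] = (v - v.mean()) / sd if sd > 0 else 0.0
    return out


def build_features(
    annotations,
    translation_table: pd.DataFrame,
    energies: pd.DataFrame,
    uorfs: pd.DataFrame | None = None,
    cis_elements: dict[str, str] | None = None,
    zscore: bool = True,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Per-transcript feature matrix with one category per feature.

    ``energies`` must carry per-transcript ``dg_ds`` and ``dg_g4`` columns
    (5'-UTR folding energies); ``uorfs`` is an optional scored uORF table.
    Missing uORF features impute to 0 (no uORF).  Returns the (optionally
    z-scored) feature frame indexed by transcript and a feature -> category
    map.
    """
    if cis_elements is None:
        cis_elements = DEFAULT_CIS_ELEMENTS
    tt = translation_table.set_index("transcript_id")
    en = energies.set_index("transcript_id")
    missing = [a.transcript_id for a in annotations if a.transcript_id not in tt.index]
    missing += [a.transcript_id for a in annotations if a.transcript_id not in en.index]
    if missing:
        raise ValueError(f"cohort mismatch; missing transcripts: {sorted(set(missing))}")
    rows = []
    cats: dict[str, str] = {}
    for ann in annotations:
        utr5 = ann.utr5_sequence
        n5 = max(len(utr5), 1)
        feat = {
            "log_rna_tpm": np.log2(tt.loc[ann.transcript_id, "rna_cds_tpm"] + 1.0),
            "utr5_len": ann.utr5_len,
            "log_utr5_len": np.log2(ann.utr5_len + 1.0),
            "cds_len": ann.cds_len,
            "log_cds_len": np.log2(ann.cds_len + 1.0),
            "frac_a": utr5.count("A") / n5,
            "frac_c": utr5.count("C") / n5,
            "frac_g": utr5.count("G") / n5,
            "frac_u": utr5.count("U") / n5,
            "frac_gc": (utr5.count("G") + utr5.count("C")) / n5,
            "frac_gg": sum(
                1 for i in range(len(utr5) - 1) if utr5[i : i + 2] == "GG"
            ) / max(n5 - 1, 1),
            "dg_ds": en.loc[ann.transcript_id, "dg_ds"],
            "dg_ds_per_nt": en.loc[ann.transcript_id, "dg_ds"] / n5,
            "dg_g4": en.loc[ann.transcript_id, "dg_g4"],
            "dg_g4_per_nt": en.loc[ann.transcript_id, "dg_g4"] / n5,
        }
        if uorfs is not None and len(uorfs):
            mine = uorfs[uorfs["transcript_id"] == ann.transcript_id]
            scored = mine[np.isfinite(mine["orfscore"].astype(float))]
            feat["n_uorfs"] = len(mine)
            feat["n_aug_uorfs"] = int((mine["start_codon"] == "AUG").sum())
            feat["n_nonaug_uorfs"] = int((mine["start_codon"] != "AUG").sum())
            feat["max_orfscore"] = (
                float(scored["orfscore"].max()) if len(scored) else 0.0
            )
        else:
            feat.update(n_uorfs=0, n_aug_uorfs=0, n_nonaug_uorfs=0, max_orfscore=0.0)
        for name, motif in cis_elements.items():
            feat[f"cis_{name.lower()}"] = len(iupac_regex(motif).findall(utr5))
        rows.append(feat)
    features = pd.DataFrame(rows, index=[a.transcript_id for a in annotations])
    cats.update(
        log_rna_tpm="abundance",
        utr5_len="length", log_utr5_len="length",
        cds_len="length", log_cds_len="length",
        frac_a="base_composition", frac_c="base_composition",
        frac_g="base_composition", frac_u="base_composition",
        frac_gc="base_composition", frac_gg="base_composition",
        dg_ds="dsRNA", dg_ds_per_nt="dsRNA",
        dg_g4="rG4", dg_g4_per_nt="rG4",
        n_uorfs="uORF", n_aug_uorfs="uORF", n_nonaug_uorfs="uORF",
        max_orfscore="uORF",
    )
    for name in cis_elements:
        cats[f"cis_{name.lower()}"] = "other"
    if zscore:
        features = zscore_columns(features)
    return features, cats


# ---------------------------------------------------------------------------
# Clustering and PCA
# ---------------------------------------------------------------------------


def cluster_transcripts(
    values: pd.DataFrame,
    k: int = 5,
    metric: str = "canberra",
) -> pd.Series:
    """Agglomerative clustering of (TE, dsRNA, rG4) z-score triples.

    Canberra dissimilarities are fed to the Ward update formula (the
    behavior of Ward-type linkage on a precomputed non-Euclidean
    dissimilarity; mathematically loose but deterministic — see
    docs/methods.md).  Cluster labels are renumbered by ascending mean of
    the last column (the quadruplex-energy z-score) for reproducibility.
    """
    if k > len(values):
        raise ValueError(f"k={k} exceeds {len(values)} observations")
    mat = zscore_columns(values)
    dist = pdist(mat.to_numpy(), metric=metric)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tree = linkage(dist, method="ward")
    raw = fcluster(tree, t=k, criterion="maxclust")
    order_col = mat.columns[-1]
    means = (
        pd.DataFrame({"cluster": raw, "v": mat[order_col].to_numpy()})
        .groupby("cluster")["v"]
        .mean()
        .sort_values(kind="stable")
    )
    relabel = {old: new + 1 for new, old in enumerate(means.index)}
    return pd.Series([relabel[c] for c in raw], index=values.index, name="cluster")


@dataclass
class PCAResult:
    coordinates: pd.DataFrame  # columns Dim.1, Dim.2, ...
    variance_explained: np.ndarray
    loadings: pd.DataFrame
    rg4_subset: pd.Series  # bool per transcript


def pca_subset(
    features: pd.DataFrame,
    rg4_feature: str = "dg_g4_per_nt",
    ds_feature: str = "dg_ds_per_nt",
    n_components: int | None = None,
) -> PCAResult:
    """PCA of the z-scored feature matrix with quadrant subsetting.

    Eigenvector signs are arbitrary, so they are fixed to make the
    quadrant rule well defined: the designated quadruplex-energy feature
    loads non-negatively on Dim.1 and the dsRNA-energy feature
    non-positively on Dim.2.  The quadruplex-marked subset is then
    Dim.1 >= 0 and Dim.2 <= 0.
    """
    if features.shape[1] < 3 or features.shape[0] < 3:
        raise ValueError("need at least 3 features and 3 transcripts")
    mat = zscore_columns(features)
    rank = np.linalg.matrix_rank(mat.to_numpy())
    if rank < min(mat.shape):
        warnings.warn(f"rank-deficient feature matrix (rank {rank}); proceeding")
    if n_components is None:
        n_components = min(mat.shape[0], mat.shape[1], max(2, rank))
    pca = PCA(n_components=n_components)
    coords = pca.fit_transform(mat.to_numpy())
    load = pca.components_.T  # feature x component
    signs = np.ones(n_components)
    if rg4_feature in mat.columns:
        i = mat.columns.get_loc(rg4_feature)
        if load[i, 0] < 0:
            signs[0] = -1
    if ds_feature in mat.columns and n_components > 1:
        i = mat.columns.get_loc(ds_feature)
        if load[i, 1] > 0:
            signs[1] = -1
    coords = coords * signs
    load = load * signs
    cols = [f"Dim.{i + 1}" for i in range(n_components)]
    coord_df = pd.DataFrame(coords, index=features.index, columns=cols)
    subset = (coord_df["Dim.1"] >= 0) & (coord_df["Dim.2"] <= 0)
    return PCAResult(
        coord_df,
        pca.explained_variance_ratio_,
        pd.DataFrame(load, index=mat.columns, columns=cols),
        subset.rename("rg4_subset"),
    )


# ---------------------------------------------------------------------------
# Predictor selection + boosted regression
# ---------------------------------------------------------------------------

DEFAULT_GBM_GRID = {
    "n_estimators": [100, 300],
    "max_depth": [2, 3],
    "learning_rate": [0.05, 0.1],
    "min_samples_leaf": [5],
}


@dataclass
class ModelReport:
    predictor_set: str
    selected: list[str]
    n_selected: int
    r2_train: float
    r2_tests: list[float]
    r2_test: float  # mean of the three test splits
    resampling_r2: np.ndarray  # 10-fold CV x 10 repeats
    best_params: dict


def _collinearity_screen(
    X: pd.DataFrame, y: np.ndarray, threshold: float = 0.85
) -> list[str]:
    """Drop one of any |correlation| > threshold pair, keeping the feature
    with the larger univariate association with the target."""
    cols = list(X.columns)
    assoc = {
        c: abs(stats.pearsonr(X[c].to_numpy(), y)[0]) if X[c].std() > 0 else 0.0
        for c in cols
    }
    keep = sorted(cols, key=lambda c: -assoc[c])
    kept: list[str] = []
    corr = X.corr().abs()
    for c in keep:
        if all(corr.loc[c, k] <= threshold for k in kept):
            kept.append(c)
    return [c for c in cols if c in kept]


def fit_rpfdist_model(
    features: pd.DataFrame,
    target: pd.Series,
    categories: dict[str, str] | None = None,
    predictor_filter: str | set[str] = "all",
    seed: int = 0,
    cv_folds: int = 10,
    cv_repeats: int = 10,
    train_fraction: float = 0.7,
    gbm_grid: dict | None = None,
    label: str | None = None,
) -> ModelReport:
    """Predictor selection and boosted regression of (log) RPFdist.

    Predictors (optionally restricted to one or more categories) are
    screened by an L1-penalized linear fit with internally cross-validated
    penalty, then pruned for collinearity; a gradient-boosted tree
    regressor is tuned by ``cv_folds``-fold CV on a 70% training split and
    evaluated on three 10% test splits.  The resampling distribution
    (``cv_folds`` x ``cv_repeats`` CV R^2 on the training split) feeds
    model comparison.
    """
    if predictor_filter != "all":
        if categories is None:
            raise ValueError("categories required to filter predictors")
        wanted = (
            {predictor_filter} if isinstance(predictor_filter, str) else set(predictor_filter)
        )
        cols = [c for c in features.columns if categories.get(c) in wanted]
    else:
        cols = list(features.columns)
    if not cols:
        raise ValueError("empty predictor set after filtering")
    X = features[cols]
    mask = np.isfinite(target.to_numpy(dtype=float))
    X, y = X.loc[mask], target.to_numpy(dtype=float)[mask]

    rng = np.random.default_rng(seed)
    n = len(y)
    perm = rng.permutation(n)
    n_train = int(round(train_fraction * n))
    train_idx = perm[:n_train]
    test_chunks = np.array_split(perm[n_train:], 3)

    Xtr, ytr = X.iloc[train_idx], y[train_idx]
    # L1 selection
    lasso = LassoCV(cv=KFold(cv_folds, shuffle=True, random_state=seed),
                    random_state=seed, max_iter=50_000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lasso.fit(Xtr.to_numpy(), ytr)
    selected = [c for c, coef in zip(cols, lasso.coef_) if abs(coef) > 1e-10]
    if not selected:
        selected = cols  # fall back to the full filtered set
    selected = _collinearity_screen(Xtr[selected], ytr)

    grid = DEFAULT_GBM_GRID if gbm_grid is None else gbm_grid
    search = GridSearchCV(
        GradientBoostingRegressor(random_state=seed),
        grid,
        cv=KFold(cv_folds, shuffle=True, random_state=seed),
        scoring="r2",
        n_jobs=1,
    )
    search.fit(Xtr[selected].to_numpy(), ytr)
    best = search.best_estimator_
    r2_train = float(best.score(Xtr[selected].to_numpy(), ytr))
    r2_tests = [
        float(best.score(X.iloc[chunk][selected].to_numpy(), y[chunk]))
        for chunk in test_chunks
        if len(chunk)
    ]
    resampling = cross_val_score(
        best,
        Xtr[selected].to_numpy(),
        ytr,
        cv=RepeatedKFold(n_splits=cv_folds, n_repeats=cv_repeats, random_state=seed),
        scoring="r2",
        n_jobs=1,
    )
    return ModelReport(
        predictor_set=label or (
            predictor_filter if isinstance(predictor_filter, str)
            else "+".join(sorted(predictor_filter))
        ),
        selected=selected,
        n_selected=len(selected),
        r2_train=r2_train,
        r2_tests=r2_tests,
        r2_test=float(np.mean(r2_tests)),
        resampling_r2=np.asarray(resampling),
        best_params=search.best_params_,
    )


def compare_models(report_a: ModelReport, report_b: ModelReport) -> float:
    """Two-sample Kolmogorov-Smirnov P value between resampling R^2
    distributions of two models fit under the same protocol."""
    a, b = report_a.resampling_r2, report_b.resampling_r2
    if len(a) != len(b):
        raise ValueError("resampling vectors must follow the same protocol")
    if np.array_equal(a, b):
        return 1.0
    return float(stats.ks_2samp(a, b).pvalue)
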