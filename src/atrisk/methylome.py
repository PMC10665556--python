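"""Differential methylation arm.

Calls differentially methylated loci (DML) between participant groups
with Welch's t-test on beta values, replicates calls across two
independent cohorts with a hypergeometric overlap test, maps the
cross-cohort union of DML to genes (DMG) through promoter/body windows,
tests gene sets for DMG over-representation, embeds samples in 2-D
(classical MDS or PCA on M-values), hierarchically clusters samples,
and trains one-vs-one random-forest classifiers of group status.

Conventions
-----------
* Beta values are methylation fractions in [0, 1]; M-values are
  ``log2(beta / (1 - beta))`` after clipping away from {0, 1}.
* A locus is a DML when the raw two-sided Welch p < alpha (default
  0.05) AND the absolute difference of group mean beta exceeds
  ``delta_beta`` (default 0.1). Raw p-values are deliberately NOT
  multiplicity-corrected at this stage: the downstream two-cohort
  replication step is the guard against false discovery.
* Annotation coordinates are 1-based. The promoter window is closed,
  [TSS - 2500, TSS + 500], oriented by gene strand (on the minus
  strand "upstream" means larger genomic coordinates).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split

from ._stats import bh_adjust, hypergeom_upper_tail

log = logging.getLogger("atrisk")

META_COLUMNS = ("group", "cohort", "cell_type", "subject")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class BetaMatrix:
    """Probes x samples methylation fractions with per-sample labels.

    ``values`` is a DataFrame indexed by probe id with one column per
    sample; ``sample_meta`` is indexed by sample id and carries
    ``group``, ``cohort``, ``cell_type`` and ``subject`` for every
    sample column.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values.to_numpy(dtype=float)
        finite = v[np.isfinite(v)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("beta values must lie in [0, 1]")
        if self.values.index.has_duplicates:
            raise ValueError("probe ids must be unique")
        missing = set(self.values.columns) - set(self.sample_meta.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)[:5]}")
        for col in META_COLUMNS:
            if col not in self.sample_meta.columns:
                raise ValueError(f"sample_meta lacks required column {col!r}")

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    def subset_samples(self, mask: pd.Series) -> "BetaMatrix":
        keep = self.sample_meta.index[mask.reindex(self.sample_meta.index, fill_value=False)]
        keep = [c for c in self.values.columns if c in set(keep)]
        return BetaMatrix(self.values[keep], self.sample_meta.loc[keep])


@dataclass
class MValueMatrix:
    """Probes x samples M-values (log2 odds of beta)."""

    values: pd.DataFrame
    sample_meta: pd.DataFrame


@dataclass
class OverlapTest:
    """Hypergeometric replication test between two cohort DML sets."""

    universe: int
    size1: int
    size2: int
    overlap: int
    p: float


@dataclass
class ClassifierReport:
    """One-vs-one random-forest result for a pair of participant groups."""

    comparison: str
    selected_features: list[str]
    cv_accuracy: float
    test_accuracy: float
    best_params: dict
    seed: int
    n_train: int = 0
    n_test: int = 0
    importances: pd.Series = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# probe filtering and transforms
# ---------------------------------------------------------------------------

def filter_probes(beta: BetaMatrix, blacklist) -> BetaMatrix:
    """Drop blacklisted probes (e.g. SNP-overlapping), preserving order.

    A generic stand-in for array-level probe QC: any upstream exclusion
    list (SNP overlap, cross-hybridising, failed detection) is supplied
    as a plain set of probe ids.
    """
    blacklist = set(blacklist)
    hit = beta.probe_ids.isin(blacklist)
    if blacklist and not hit.any():
        log.warning("probe blacklist (%d ids) is disjoint from the matrix", len(blacklist))
    kept = beta.values.loc[~hit]
    if kept.shape[0] == 0:
        raise ValueError("all probes removed by blacklist")
    return BetaMatrix(kept, beta.sample_meta)


def beta_to_m(beta: BetaMatrix, clip: float = 1e-3) -> MValueMatrix:
    """M = log2(beta' / (1 - beta')) with beta' clipped to [clip, 1 - clip]."""
    if not 0 < clip < 0.5:
        raise ValueError("clip must lie in (0, 0.5)")
    b = beta.values.clip(lower=clip, upper=1 - clip)
    m = np.log2(b / (1 - b))
    return MValueMatrix(m, beta.sample_meta)


# ---------------------------------------------------------------------------
# DML calling
# ---------------------------------------------------------------------------

def welch_t(group_a, group_b) -> tuple[float, float]:
    """Two-sided Welch t-test (Welch-Satterthwaite df) for one locus.

    Returns ``(nan, nan)`` for degenerate input (fewer than two
    non-missing values per group, or zero variance in both groups).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        return float("nan"), float("nan")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float("nan"), float("nan")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def _pair_label(a: str, b: str) -> str:
    return f"{a}_vs_{b}"


def _welch_vectorised(A: np.ndarray, B: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise Welch t on two probes x samples blocks with NaN support."""
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(A, B, axis=1, equal_var=False, nan_policy="omit")
        delta = np.nanmean(A, axis=1) - np.nanmean(B, axis=1)
    return np.asarray(t, float), np.asarray(p, float), delta


def call_dml(
    beta: BetaMatrix,
    comparison,
    alpha: float = 0.05,
    delta_beta: float = 0.1,
    mode: str = "pairwise",
) -> pd.DataFrame:
    """Call DML per cohort x cell-type stratum.

    Parameters
    ----------
    comparison:
        Two group names for a single pairwise contrast, or three for
        the three-group analysis. With three groups, ``mode``
        selects how per-pair calls combine: ``"any_pair"`` flags a
        locus that passes both gates in at least one of the three
        pairwise contrasts; ``"pairwise"`` just reports each contrast.
    alpha, delta_beta:
        The two gates: raw p < alpha and \\|difference of mean beta\\|
        > delta_beta. No multiple-testing correction is applied.

    Returns
    -------
    Long-form DataFrame with one row per probe x stratum x pair,
    columns ``probe, cohort, cell_type, comparison, mean_a, mean_b,
    delta_beta, t, p, called`` (plus ``called_any`` in any_pair mode).
    """
    groups = list(comparison)
    if mode not in ("pairwise", "any_pair"):
        raise ValueError(f"unknown mode {mode!r}")
    present = set(beta.sample_meta["group"])
    for g in groups:
        if g not in present:
            raise ValueError(f"group {g!r} absent from sample metadata")
    if len(groups) == 2:
        pairs = [(groups[0], groups[1])]
    else:
        pairs = [(groups[i], groups[j]) for i in range(len(groups)) for j in range(i + 1, len(groups))]

    meta = beta.sample_meta.loc[list(beta.values.columns)]
    out = []
    for (cohort, cell_type), stratum in meta.groupby(["cohort", "cell_type"], sort=True):
        cols_by_group = {
            g: stratum.index[stratum["group"] == g].tolist() for g in groups
        }
        for ga, gb in pairs:
            ca, cb = cols_by_group[ga], cols_by_group[gb]
            if len(ca) < 2 or len(cb) < 2:
                log.info("stratum (%s, %s) pair %s/%s skipped: too few samples", cohort, cell_type, ga, gb)
                continue
            A = beta.values[ca].to_numpy(dtype=float)
            B = beta.values[cb].to_numpy(dtype=float)
            t, p, delta = _welch_vectorised(A, B)
            degenerate = ~np.isfinite(p)
            n_deg = int(degenerate.sum())
            if n_deg:
                log.info(
                    "stratum (%s, %s) pair %s/%s: %d degenerate loci excluded",
                    cohort, cell_type, ga, gb, n_deg,
                )
            called = np.isfinite(p) & (p < alpha) & (np.abs(delta) > delta_beta)
            out.append(pd.DataFrame({
                "probe": beta.probe_ids,
                "cohort": cohort,
                "cell_type": cell_type,
                "comparison": _pair_label(ga, gb),
                "mean_a": np.nanmean(A, axis=1),
                "mean_b": np.nanmean(B, axis=1),
                "delta_beta": delta,
                "t": t,
                "p": p,
                "called": called,
            }))
    if not out:
        raise ValueError("no stratum had enough samples for the requested comparison")
    res = pd.concat(out, ignore_index=True)
    if mode == "any_pair" and len(groups) > 2:
        any_called = res.groupby(["probe", "cohort", "cell_type"])["called"].transform("any")
        res["called_any"] = any_called
    return res


def called_probes(dml: pd.DataFrame, cohort=None, cell_type=None, any_pair: bool = False) -> set:
    """Probe ids flagged as DML, optionally restricted to one stratum."""
    d = dml
    if cohort is not None:
        d = d[d["cohort"] == cohort]
    if cell_type is not None:
        d = d[d["cell_type"] == cell_type]
    col = "called_any" if (any_pair and "called_any" in d.columns) else "called"
    return set(d.loc[d[col], "probe"])


# ---------------------------------------------------------------------------
# two-cohort replication
# ---------------------------------------------------------------------------

def cross_cohort(dml1, dml2, universe: int) -> tuple[OverlapTest, set]:
    """Hypergeometric replication of DML calls across two cohorts.

    The overlap of the two cohort call sets is tested against drawing
    the second set at random from the ``universe`` of filtered loci;
    the union of the two sets is returned for the DMG mapping step.
    """
    s1, s2 = set(dml1), set(dml2)
    union = s1 | s2
    if universe < len(union):
        raise ValueError("universe smaller than the union of the DML sets")
    m = len(s1 & s2)
    test = OverlapTest(
        universe=universe, size1=len(s1), size2=len(s2), overlap=m,
        p=hypergeom_upper_tail(universe, len(s1), len(s2), m),
    )
    return test, union


# ---------------------------------------------------------------------------
# DMG mapping
# ---------------------------------------------------------------------------

ANNOTATION_COLUMNS = ("probe_id", "chrom", "pos", "strand", "gene", "tss", "gene_start", "gene_end")


def read_annotation(path) -> pd.DataFrame:
    """Read the BED-like probe annotation TSV (1-based coordinates)."""
    ann = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(ANNOTATION_COLUMNS) - set(ann.columns)
    if missing:
        raise ValueError(f"annotation lacks columns: {sorted(missing)}")
    for i, row in enumerate(ann.itertuples(index=False), start=2):  # header is line 1
        if row.strand not in ("+", "-"):
            raise ValueError(f"annotation line {i}: bad strand {row.strand!r}")
    return ann


def map_dmg(probes, annotation: pd.DataFrame, promoter_window=(-2500, 500)) -> pd.DataFrame:
    """Map DML probes to genes via promoter/body windows.

    A probe supports a gene's promoter when its position falls inside
    the closed, strand-oriented window ``[TSS - 2500, TSS + 500]``;
    otherwise it supports the gene body when it lies within the gene
    interval. Probes without annotation are dropped (count logged).

    Returns a DataFrame with columns ``gene, probe, region``.
    """
    lo, hi = promoter_window
    probes = set(probes)
    ann = annotation[annotation["probe_id"].isin(probes)]
    n_drop = len(probes) - ann["probe_id"].nunique()
    if n_drop:
        log.info("map_dmg: %d probes without annotation dropped", n_drop)
    rows = []
    for row in ann.itertuples(index=False):
        offset = row.pos - row.tss if row.strand == "+" else row.tss - row.pos
        if lo <= offset <= hi:
            rows.append((row.gene, row.probe_id, "promoter"))
        elif row.gene_start <= row.pos <= row.gene_end:
            rows.append((row.gene, row.probe_id, "body"))
    return pd.DataFrame(rows, columns=["gene", "probe", "region"]).drop_duplicates()


def dmg_genes(dmg: pd.DataFrame) -> set:
    return set(dmg["gene"])


# ---------------------------------------------------------------------------
# pathway over-representation
# ---------------------------------------------------------------------------

def read_gmt(path) -> dict:
    """Read a GMT gene-set collection into {set id: set of genes}."""
    import gseapy

    return {k: set(v) for k, v in gseapy.read_gmt(str(path)).items()}


def pathway_enrichment(genes, genesets: dict, background, fdr_threshold: float = 0.1) -> pd.DataFrame:
    """Hypergeometric over-representation of DMG in each gene set.

    Each set is intersected with the ``background`` gene universe
    before testing; empty sets are skipped (logged). Benjamini-
    Hochberg adjustment is applied across the tested sets and sets
    are flagged significant at ``fdr < fdr_threshold``.
    """
    bg = set(background)
    query = set(genes) & bg
    rows = []
    for name, members in genesets.items():
        members = set(members) & bg
        if not members:
            log.info("gene set %r empty after background intersection; skipped", name)
            continue
        m = len(query & members)
        p = hypergeom_upper_tail(len(bg), len(members), len(query), m)
        rows.append((name, len(members), m, p))
    res = pd.DataFrame(rows, columns=["set_id", "set_size", "overlap", "p"])
    if len(res):
        res["fdr"] = bh_adjust(res["p"].to_numpy())
        res["significant"] = res["fdr"] < fdr_threshold
        res = res.sort_values("p", ignore_index=True)
    return res


# ---------------------------------------------------------------------------
# embeddings and clustering
# ---------------------------------------------------------------------------

def _impute_rows(values: pd.DataFrame) -> pd.DataFrame:
    """Replace missing entries by the per-probe mean (logged)."""
    n_missing = int(values.isna().to_numpy().sum())
    if n_missing:
        log.info("embedding: imputing %d missing values with per-probe means", n_missing)
        values = values.T.fillna(values.mean(axis=1)).T
    return values


def embed(m: MValueMatrix, method: str = "mds", features=None, n_components: int = 2) -> pd.DataFrame:
    """2-D sample coordinates by classical MDS (PCoA) or PCA.

    Classical MDS operates on Euclidean distances between samples
    across all loci; PCA is meant for defined DML subsets
    (``features``). Coordinates are deterministic up to sign.
    """
    values = m.values if features is None else m.values.loc[list(features)]
    values = _impute_rows(values)
    X = values.T.to_numpy(dtype=float)  # samples x probes
    if X.shape[0] < 3:
        raise ValueError("need at least 3 samples to embed")
    if method == "pca":
        coords = PCA(n_components=n_components, svd_solver="full").fit_transform(X - X.mean(axis=0))
    elif method == "mds":
        from scipy.spatial.distance import pdist, squareform
        from skbio.stats.ordination import pcoa

        D = squareform(pdist(X))
        coords = pcoa(D, number_of_dimensions=n_components).samples.to_numpy()[:, :n_components]
    else:
        raise ValueError(f"unknown embedding method {method!r}")
    return pd.DataFrame(
        coords, index=values.columns, columns=[f"dim{i + 1}" for i in range(n_components)]
    )


def hier_cluster(m: MValueMatrix, features, method: str = "complete", metric: str = "euclidean") -> dict:
    """Hierarchical clustering of samples on a DML feature subset.

    Returns the scipy linkage matrix together with the sample order
    and the linkage parameters, ready for dendrogram/heatmap export.
    """
    features = list(features)
    if not features:
        raise ValueError("feature list is empty")
    values = _impute_rows(m.values.loc[features])
    X = values.T.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples to cluster")
    from scipy.cluster import hierarchy

    Z = hierarchy.linkage(X, method=method, metric=metric)
    order = hierarchy.leaves_list(Z)
    return {
        "linkage": Z,
        "samples": list(values.columns),
        "leaf_order": [values.columns[i] for i in order],
        "method": method,
        "metric": metric,
    }


# ---------------------------------------------------------------------------
# one-vs-one classification
# ---------------------------------------------------------------------------

DEFAULT_RF_GRID = {"n_estimators": [200, 500], "max_features": ["sqrt", 0.333]}


def classify_one_vs_one(
    m: MValueMatrix,
    features,
    pair,
    seed: int,
    test_size: float = 0.3,
    cv: int = 10,
    grid: dict | None = None,
    min_per_class: int = 4,
    top_fraction: float = 0.1,
) -> ClassifierReport:
    """Random-forest one-vs-one classifier on previously called DML.

    Samples of the two groups are split 70/30 (stratified), a small
    hyperparameter grid is tuned by stratified k-fold cross-validation
    on the training part (k shrinks if a class is small), and accuracy
    on the held-out part is reported together with the top fraction of
    features by impurity importance — the feature list feeds the
    combined-model PCA.
    """
    ga, gb = pair
    meta = m.sample_meta.loc[list(m.values.columns)]
    mask = meta["group"].isin([ga, gb])
    cols = meta.index[mask]
    y = meta.loc[cols, "group"].to_numpy()
    for g in (ga, gb):
        n = int((y == g).sum())
        if n < 2:
            raise ValueError(f"group {g!r} has {n} samples; need at least 2")
        if n < min_per_class:
            raise ValueError(f"group {g!r} has {n} samples; minimum is {min_per_class}")
    features = list(features)
    X = _impute_rows(m.values.loc[features])[cols].T.to_numpy(dtype=float)

    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=test_size, stratify=y, random_state=seed
    )
    min_class = min(np.bincount(pd.factorize(y_tr)[0]))
    n_splits = max(2, min(cv, int(min_class)))
    grid = DEFAULT_RF_GRID if grid is None else grid
    search = GridSearchCV(
        RandomForestClassifier(random_state=seed),
        grid,
        cv=StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed),
        scoring="accuracy",
        n_jobs=1,
    )
    search.fit(X_tr, y_tr)
    best = search.best_estimator_
    test_acc = float(best.score(X_te, y_te))
    importances = pd.Series(best.feature_importances_, index=features)
    n_top = max(1, int(np.ceil(top_fraction * len(features))))
    selected = importances.sort_values(ascending=False).head(n_top).index.tolist()
    return ClassifierReport(
        comparison=_pair_label(ga, gb),
        selected_features=selected,
        cv_accuracy=float(search.best_score_),
        test_accuracy=test_acc,
        best_params=dict(search.best_params_),
        seed=seed,
        n_train=len(y_tr),
        n_test=len(y_te),
        importances=importances,
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_beta_matrix(values_path, meta_path) -> BetaMatrix:
    """Read a probes x samples beta TSV and its sample sheet."""
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    return BetaMatrix(values, meta)


def write_beta_matrix(beta: BetaMatrix, values_path, meta_path) -> None:
    beta.values.to_csv(values_path, sep="\t")
    beta.sample_meta.to_csv(meta_path, sep="\t")
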