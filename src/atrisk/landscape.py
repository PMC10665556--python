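"""CD4+ T-cell phenotype landscape (metaclustering) arm.

Builds a cross-subject landscape from six phenotyping markers
(CD45RA, CD38, CCR4, CCR6, CXCR3, CCR7):

1. arcsinh-transform raw intensities (``y = asinh(a + b*x)``,
   defaults a=0, b=1/150);
2. cluster each subject's events separately on a k-nearest-neighbour
   graph with modularity community detection (k-means fallback for
   tiny samples);
3. summarise each individual cluster with >1% frequency as a z-score
   profile of marker expression against that subject's total CD4
   events;
4. metacluster profiles across subjects with Ward linkage on Euclidean
   distance and cut the dendrogram into a fixed number of aligned
   clusters (ACs; default 10);
5. overlay tetramer-positive (Tmr+) events — which were concatenated
   to each subject's total-CD4 table before clustering — and compute
   per-subject AC fractions for total CD4 and per antigen;
6. compare per-subject AC fractions between participant groups with
   the Wilcoxon rank-sum test.

Subjects contribute to an antigen's AC statistics only when they have
at least 8 events of that specificity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.neighbors import NearestNeighbors

from ._stats import wilcoxon_rank_sum
from .types import DEFAULT_PAIRS, GroupComparison

log = logging.getLogger("atrisk")

MARKERS = ("CD45RA", "CD38", "CCR4", "CCR6", "CXCR3", "CCR7")
ARCSINH_B = 1.0 / 150.0
MIN_CLUSTER_FRAC = 0.01
MIN_TMR_EVENTS = 8
DEFAULT_CUT = 10


def transform(x, a: float = 0.0, b: float = ARCSINH_B) -> np.ndarray:
    """arcsinh transform of raw intensities: ``asinh(a + b*x)``."""
    if b <= 0:
        raise ValueError("b must be positive")
    return np.arcsinh(a + b * np.asarray(x, dtype=float))


def inverse_transform(y, a: float = 0.0, b: float = ARCSINH_B) -> np.ndarray:
    """Raw intensity from transformed value: ``x = (sinh(y) - a)/b``."""
    if b <= 0:
        raise ValueError("b must be positive")
    return (np.sinh(np.asarray(y, dtype=float)) - a) / b


# ---------------------------------------------------------------------------
# per-subject clustering
# ---------------------------------------------------------------------------

def cluster_sample(
    X,
    k_neighbors: int = 30,
    seed: int = 0,
    method: str = "graph",
    n_clusters: int = 8,
) -> np.ndarray:
    """Cluster one subject's events in transformed marker space.

    ``method="graph"`` builds an undirected k-nearest-neighbour graph
    and partitions it by modularity (Leiden); this is the working
    analogue of PhenoGraph-style clustering and is deterministic under
    ``seed``. ``method="kmeans"`` is a fallback for very small samples
    where a kNN graph is degenerate.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be events x markers")
    n = X.shape[0]
    if n == 0:
        raise ValueError("no events to cluster")
    if method == "kmeans":
        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=min(n_clusters, n), n_init=10, random_state=seed)
        return km.fit_predict(X)
    if method != "graph":
        raise ValueError(f"unknown clustering method {method!r}")
    if n < k_neighbors + 1:
        raise ValueError(f"need at least k_neighbors+1={k_neighbors + 1} events, got {n}")
    import igraph
    import leidenalg

    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(X)
    _, idx = nn.kneighbors(X)
    edges = {(min(i, j), max(i, j)) for i, row in enumerate(idx) for j in row[1:]}
    g = igraph.Graph(n=n, edges=sorted(edges), directed=False)
    part = leidenalg.find_partition(g, leidenalg.ModularityVertexPartition, seed=seed)
    return np.asarray(part.membership, dtype=int)


# ---------------------------------------------------------------------------
# cluster profiles
# ---------------------------------------------------------------------------

def profile_and_filter(
    events: pd.DataFrame,
    labels,
    subject: str,
    markers=MARKERS,
    min_frac: float = MIN_CLUSTER_FRAC,
    exclude_tmr_from_reference: bool = False,
) -> pd.DataFrame:
    """Per-cluster z-score profiles versus the subject's total CD4 events.

    z = (cluster mean - subject mean) / subject SD per marker, in
    transformed space (population SD, ddof=0). Clusters at or below
    ``min_frac`` of the subject's events are dropped. Tmr+ events are
    part of the reference statistics by default (they are a negligible
    fraction of the concatenated table); ``exclude_tmr_from_reference``
    removes them from the mean/SD only.

    Returns a DataFrame with columns ``subject, cluster, frequency``
    and one z column per marker.
    """
    labels = np.asarray(labels)
    if len(labels) != len(events):
        raise ValueError("labels and events length mismatch")
    ref = events
    if exclude_tmr_from_reference and "tmr" in events.columns:
        ref = events[~events["tmr"].astype(bool)]
    ref_mean = ref[list(markers)].mean(axis=0)
    ref_sd = ref[list(markers)].std(axis=0, ddof=0)
    zero_sd = ref_sd == 0
    if zero_sd.any():
        log.warning("subject %s: zero SD for markers %s; z set to 0",
                    subject, list(ref_sd.index[zero_sd]))
    rows = []
    n_total = len(events)
    for lab in np.unique(labels):
        sub = events.loc[labels == lab, list(markers)]
        freq = len(sub) / n_total
        if freq <= min_frac:
            continue
        z = (sub.mean(axis=0) - ref_mean) / ref_sd.replace(0, np.nan)
        z = z.fillna(0.0)
        rows.append({"subject": subject, "cluster": int(lab), "frequency": freq,
                     **{mk: z[mk] for mk in markers}})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# metaclustering into aligned clusters
# ---------------------------------------------------------------------------

@dataclass
class AlignedClusterModel:
    """Ward metaclustering of per-subject cluster profiles."""

    linkage: np.ndarray
    profiles: pd.DataFrame  # with an added "ac" column
    mapping: dict  # (subject, cluster) -> ac id (1-based)
    cut: int

    def assign(self, subject: str, cluster: int):
        """AC id for one individual cluster; None if unaligned (<1% cluster)."""
        return self.mapping.get((subject, int(cluster)))


def metacluster(profiles: pd.DataFrame, cut: int = DEFAULT_CUT, markers=MARKERS) -> AlignedClusterModel:
    """Ward-linkage metaclustering of z-score profiles across subjects.

    Euclidean distance on the z vectors; the dendrogram is cut into
    exactly ``cut`` aligned clusters. The fixed default of 10 mirrors
    a landscape resolution at which distinct helper phenotypes
    separate, but the right count is data-dependent and configurable.
    """
    if len(profiles) < cut:
        raise ValueError(f"cannot cut {len(profiles)} profiles into {cut} aligned clusters")
    if len(profiles) == 1:
        Z = np.empty((0, 4))
        acs = np.array([1])
    else:
        Z = hierarchy.linkage(profiles[list(markers)].to_numpy(dtype=float), method="ward",
                              metric="euclidean")
        acs = hierarchy.fcluster(Z, t=cut, criterion="maxclust")
    profiles = profiles.copy()
    profiles["ac"] = acs
    mapping = {
        (r.subject, int(r.cluster)): int(r.ac) for r in profiles.itertuples(index=False)
    }
    return AlignedClusterModel(linkage=Z, profiles=profiles, mapping=mapping, cut=cut)


def assign_events(model: AlignedClusterModel, events: pd.DataFrame) -> pd.DataFrame:
    """Attach the aligned-cluster id to each event (NaN when unaligned)."""
    events = events.copy()
    events["ac"] = [
        model.assign(s, c) for s, c in zip(events["subject"], events["cluster"])
    ]
    return events


# ---------------------------------------------------------------------------
# AC frequencies and group comparisons
# ---------------------------------------------------------------------------

def ac_frequencies(
    events: pd.DataFrame,
    model: AlignedClusterModel,
    min_tmr_events: int = MIN_TMR_EVENTS,
) -> pd.DataFrame:
    """Per-subject AC fractions for total CD4 and for each Tmr antigen.

    Fractions are events in the AC divided by the subject's total
    events of that class (all CD4 events, or all Tmr+ events of one
    antigen). Subjects with fewer than ``min_tmr_events`` events of an
    antigen are excluded from that antigen's statistics. Every AC of
    the fitted model appears for every retained subject (zero-filled),
    so downstream rank tests see complete per-subject vectors.
    """
    if "ac" not in events.columns:
        events = assign_events(model, events)
    all_acs = sorted({ac for ac in model.mapping.values()})
    rows = []
    for subject, sub in events.groupby("subject", sort=True):
        group = sub["group"].iloc[0]
        classes = {"total": sub}
        if "tmr" in sub.columns:
            for antigen, tsub in sub[sub["tmr"].astype(bool)].groupby("antigen"):
                classes[str(antigen)] = tsub
        for cls, csub in classes.items():
            n = len(csub)
            if cls != "total" and n < min_tmr_events:
                log.info("subject %s: %d %s events < %d; excluded", subject, n, cls, min_tmr_events)
                continue
            counts = csub["ac"].value_counts()
            for ac in all_acs:
                rows.append((subject, group, cls, ac, counts.get(ac, 0) / n))
    return pd.DataFrame(rows, columns=["subject", "group", "class", "ac", "fraction"])


def compare_ac(freqs: pd.DataFrame, pairs=DEFAULT_PAIRS, cls: str = "total") -> list[GroupComparison]:
    """Wilcoxon rank-sum comparison of per-subject AC fractions.

    One test per aligned cluster per group pair, within one event
    class (``"total"`` or an antigen name). Pairs with fewer than two
    subjects on either side are skipped (logged).
    """
    sub = freqs[freqs["class"] == cls]
    out = []
    for ac, acsub in sub.groupby("ac", sort=True):
        for ga, gb in pairs:
            a = acsub.loc[acsub["group"] == ga, "fraction"].to_numpy(dtype=float)
            b = acsub.loc[acsub["group"] == gb, "fraction"].to_numpy(dtype=float)
            if len(a) < 2 or len(b) < 2:
                log.info("AC%s %s vs %s skipped: <2 subjects per group", ac, ga, gb)
                continue
            stat, p = wilcoxon_rank_sum(a, b)
            out.append(GroupComparison(
                comparison=f"{ga}_vs_{gb}", outcome=f"{cls}:AC{ac}",
                estimate=float(np.mean(a) - np.mean(b)), p=p,
                method="wilcoxon_rank_sum",
            ))
    return out


# ---------------------------------------------------------------------------
# end-to-end convenience
# ---------------------------------------------------------------------------

def run_landscape(
    event_tables: list[pd.DataFrame],
    k_neighbors: int = 30,
    cut: int = DEFAULT_CUT,
    seed: int = 0,
    arcsinh_a: float = 0.0,
    arcsinh_b: float = ARCSINH_B,
    min_cluster_frac: float = MIN_CLUSTER_FRAC,
    min_tmr_events: int = MIN_TMR_EVENTS,
    method: str = "graph",
) -> tuple[AlignedClusterModel, pd.DataFrame, pd.DataFrame]:
    """Full landscape pipeline over per-subject raw event tables.

    Each table must carry the six markers (raw intensities) plus
    ``subject``, ``group`` and optionally ``tmr``/``antigen`` columns.
    Returns the fitted model, the concatenated events with cluster and
    AC assignments, and the AC-frequency table.
    """
    profiles = []
    labelled = []
    for i, ev in enumerate(event_tables):
        ev = ev.copy().reset_index(drop=True)
        subject = str(ev["subject"].iloc[0])
        T = np.column_stack([
            transform(ev[mk].to_numpy(), a=arcsinh_a, b=arcsinh_b) for mk in MARKERS
        ])
        tdf = ev.copy()
        for j, mk in enumerate(MARKERS):
            tdf[mk] = T[:, j]
        labels = cluster_sample(T, k_neighbors=k_neighbors, seed=seed + i, method=method)
        tdf["cluster"] = labels
        labelled.append(tdf)
        profiles.append(profile_and_filter(tdf, labels, subject, min_frac=min_cluster_frac))
    profiles = pd.concat(profiles, ignore_index=True)
    model = metacluster(profiles, cut=cut)
    events = assign_events(model, pd.concat(labelled, ignore_index=True))
    freqs = ac_frequencies(events, model, min_tmr_events=min_tmr_events)
    return model, events, freqs
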