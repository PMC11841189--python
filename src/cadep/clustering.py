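"""k-means clustering of log2FC response profiles with gap-statistic k selection.

Each Ca2+-dependent gene contributes a two-dimensional profile
(log2FC under H2O2, log2FC under H2O2 + LaCl3), unscaled: the clusters group
raw response patterns (strict up/down, partial up/down, antagonistic).  The
number of clusters is fixed beforehand with the gap statistic (Tibshirani,
Walther & Hastie): Gap(k) = E*[log W_k] - log W_k against B uniform reference
datasets drawn over each feature's observed range, choosing the smallest k
with Gap(k) >= Gap(k+1) - s_{k+1}.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)


@dataclass
class ClusterModel:
    k: int
    labels: np.ndarray
    centroids: np.ndarray
    within_ss: float
    gene_ids: list[str] | None = None

    def assignments(self) -> dict[str, int]:
        if self.gene_ids is None:
            raise ValueError("model was fitted without gene ids")
        return dict(zip(self.gene_ids, (int(v) for v in self.labels)))


@dataclass
class GapCurve:
    k_values: list[int]
    gap: list[float]
    sk: list[float]
    B: int
    chosen_k: int
    log_wk: list[float] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            dict(k=self.k_values, gap=self.gap, sk=self.sk, log_wk=self.log_wk)
        )


def zscale(X: np.ndarray) -> np.ndarray:
    """Column-wise z-scaling (population SD); constant columns untouched.

    Off by default throughout: the profile features are log2 fold changes on
    a common scale, and the clusters should reflect raw response magnitude.
    """
    X = np.asarray(X, dtype=float)
    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (X - X.mean(axis=0)) / sd


def kmeans_fit(
    X: np.ndarray,
    k: int,
    seed: int = 123,
    n_restarts: int = 25,
    gene_ids: list[str] | None = None,
    scale: bool = False,
) -> ClusterModel:
    """Lloyd k-means from k-means++ starts; best of ``n_restarts`` by W_k."""
    X = np.asarray(X, dtype=float)
    if scale:
        X = zscale(X)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    if np.isnan(X).any():
        raise ValueError("X contains NaN")
    n = X.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"need 1 <= k <= n rows (k={k}, n={n})")
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=n_restarts,
        algorithm="lloyd",
        random_state=seed,
    ).fit(X)
    return ClusterModel(
        k=k,
        labels=km.labels_.copy(),
        centroids=km.cluster_centers_.copy(),
        within_ss=float(km.inertia_),
        gene_ids=list(gene_ids) if gene_ids is not None else None,
    )


def gap_select_k(
    X: np.ndarray,
    k_max: int = 10,
    B: int = 100,
    seed: int = 123,
    n_restarts: int = 10,
    ref_restarts: int = 2,
    scale: bool = False,
) -> GapCurve:
    """Gap-statistic curve over k = 1..k_max with the one-standard-error rule.

    Reference datasets are uniform over each feature's observed range;
    s_k = sd_b(log W_kb) * sqrt(1 + 1/B).  chosen_k is the smallest k with
    Gap(k) >= Gap(k+1) - s_{k+1}, falling back to argmax Gap when no k
    qualifies.  Deterministic given the seed.
    """
    X = np.asarray(X, dtype=float)
    if scale:
        X = zscale(X)
    if k_max < 1 or B < 1:
        raise ValueError("k_max and B must be >= 1")
    lo = X.min(axis=0)
    hi = X.max(axis=0)
    if np.all(hi - lo == 0):
        raise ValueError("X is constant in every feature; gap statistic undefined")
    k_max = min(k_max, X.shape[0])
    ks = list(range(1, k_max + 1))

    log_wk = [
        np.log(kmeans_fit(X, k, seed=seed, n_restarts=n_restarts).within_ss)
        for k in ks
    ]
    rng = np.random.default_rng(seed)
    ref_log = np.empty((B, len(ks)))
    for b in range(B):
        Xb = rng.uniform(lo, hi, size=X.shape)
        for j, k in enumerate(ks):
            ref_log[b, j] = np.log(
                kmeans_fit(Xb, k, seed=seed, n_restarts=ref_restarts).within_ss
            )
    gap = ref_log.mean(axis=0) - np.array(log_wk)
    sk = ref_log.std(axis=0, ddof=0) * np.sqrt(1.0 + 1.0 / B)

    chosen = None
    for j in range(len(ks) - 1):
        if gap[j] >= gap[j + 1] - sk[j + 1]:
            chosen = ks[j]
            break
    if chosen is None:
        chosen = ks[int(np.argmax(gap))]
        logger.info("gap rule satisfied by no k <= %d; using argmax", k_max)
    return GapCurve(
        k_values=ks,
        gap=[float(g) for g in gap],
        sk=[float(s) for s in sk],
        B=B,
        chosen_k=int(chosen),
        log_wk=[float(w) for w in log_wk],
    )


def _pattern_label(dep_class: str, direction: str) -> str:
    base = {
        "STRICT": "strict",
        "PARTIAL_ADDITIVE": "partial",
        "ENHANCED": "enhanced",
        "ANTAGONISTIC": "antagonistic",
        "INDEPENDENT": "independent",
    }.get(dep_class, dep_class.lower())
    if base == "antagonistic":
        return base
    return f"{base}-{direction.lower()}"


def summarize_clusters(
    model: ClusterModel,
    profiles: pd.DataFrame,
    dep_classes: pd.Series | None = None,
    directions: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-cluster mean +/- SE of each profile column plus a pattern label.

    SE = sd / sqrt(n) with ddof=1; a singleton cluster's SE is reported as 0
    and flagged (``se_flagged``) so downstream tables stay numeric.  The
    pattern label comes from the dominant dependency class (and response
    direction) among cluster members when classes are supplied.
    """
    if len(profiles) != len(model.labels):
        raise ValueError("profiles and model assignments differ in length")
    rows = []
    for c in range(model.k):
        mask = model.labels == c
        n = int(mask.sum())
        row: dict = {"cluster": c, "n": n, "se_flagged": n == 1}
        if n == 1:
            logger.warning("cluster %d is a singleton; SE reported as 0", c)
        for col in profiles.columns:
            vals = profiles.loc[mask, col].to_numpy(dtype=float)
            row[f"mean_{col}"] = float(vals.mean()) if n else float("nan")
            row[f"se_{col}"] = (
                float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
            )
        if dep_classes is not None and n:
            sub = pd.Series(np.asarray(dep_classes, dtype=object)[mask])
            dominant = sub.value_counts().idxmax()
            if directions is not None:
                dirs = pd.Series(np.asarray(directions, dtype=object)[mask])
                direction = str(dirs.value_counts().idxmax()).lower()
            else:
                direction = "up" if row.get("mean_lfc_h2o2", 0.0) >= 0 else "down"
            row["pattern"] = _pattern_label(str(dominant), direction)
        rows.append(row)
    return pd.DataFrame(rows)
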