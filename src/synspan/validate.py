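"""Confounder diagnostics: does phenotype, not species/subject, drive clusters?

Four instruments, mirroring the validation battery applied to the fitted
embedding: silhouette scores of the latent space under alternative
partitions (cluster vs species vs subject), within- vs between-cluster
cross-species earth mover's distances per marker, coefficient-of-variation
comparison of mono- vs multi-species pooling, and antibody reactivity /
species-mean tests on subject-level pseudo-bulk.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import silhouette_samples
from statsmodels.stats.multitest import multipletests

from .events import EventTable

logger = logging.getLogger(__name__)


def silhouette_by_partition(latent: np.ndarray, partition, sample_n: int = 20000,
                            seed: int = 0) -> float:
    """Mean silhouette of `partition` on a seeded subsample of the embedding.

    Euclidean metric; silhouette of an event alone in its group is 0.
    A full-data silhouette is O(n^2), so a subsample of ``sample_n``
    events is scored.
    """
    latent = np.asarray(latent)
    labels = np.asarray(partition)
    if len(labels) != len(latent):
        raise ValueError("partition length does not match embedding")
    if sample_n < 2:
        raise ValueError("sample_n must be >= 2")
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette undefined for a single group")
    rng = np.random.default_rng(seed)
    if len(latent) > sample_n:
        idx = rng.choice(len(latent), size=sample_n, replace=False)
        latent, labels = latent[idx], labels[idx]
        if len(np.unique(labels)) < 2:  # pathological subsample
            raise ValueError("subsample collapsed to a single group")
    return float(np.mean(silhouette_samples(latent, labels)))


def emd_1d(x, y) -> float:
    """1-Wasserstein distance between two empirical 1-D distributions."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample")
    return float(stats.wasserstein_distance(x, y))


def emd_within_between(table: EventTable, labels, max_cell_events: int = 1000,
                       seed: int = 0) -> pd.DataFrame:
    """Cross-species marker EMDs within vs between clusters, per marker.

    For every marker, the EMD between the expression of two different
    species is collected for all (cluster, species-pair) combinations
    ("within", same cluster) and for all pairs of distinct clusters
    ("between").  A one-sided Wilcoxon rank-sum tests within < between.
    Returns a per-marker frame with mean EMDs and p-values; frame.attrs
    carries the pooled overall test.
    """
    labels = np.asarray(labels)
    species = table.species.to_numpy()
    if len(np.unique(species)) < 2:
        raise ValueError("need >= 2 species")
    clusters = np.unique(labels)
    if len(clusters) < 2:
        raise ValueError("need >= 2 clusters to form the between set")
    rng = np.random.default_rng(seed)
    X = table.intensities

    # index events by (cluster, species), subsampled for tractability
    cells: dict[tuple, np.ndarray] = {}
    for c in clusters:
        in_c = np.flatnonzero(labels == c)
        for sp in np.unique(species[in_c]):
            idx = in_c[species[in_c] == sp]
            if len(idx) > max_cell_events:
                idx = rng.choice(idx, size=max_cell_events, replace=False)
            cells[(c, sp)] = idx

    keys = sorted(cells.keys(), key=lambda t: (str(t[0]), str(t[1])))
    rows = []
    pooled_within: list[float] = []
    pooled_between: list[float] = []
    for m, marker in enumerate(table.marker_names):
        col = X[:, m]
        within, between = [], []
        for i in range(len(keys)):
            c1, s1 = keys[i]
            for j in range(i + 1, len(keys)):
                c2, s2 = keys[j]
                if s1 == s2:
                    continue
                d = emd_1d(col[cells[keys[i]]], col[cells[keys[j]]])
                (within if c1 == c2 else between).append(d)
        if not within:
            logger.warning("marker %s: no within-cluster species pair", marker)
            continue
        stat_p = stats.mannwhitneyu(within, between, alternative="less")[1]
        rows.append({
            "marker": marker,
            "emd_within": float(np.mean(within)),
            "emd_between": float(np.mean(between)),
            "n_within": len(within),
            "n_between": len(between),
            "p_within_lt_between": float(stat_p),
        })
        pooled_within.extend(within)
        pooled_between.extend(between)
    frame = pd.DataFrame(rows)
    overall_p = float(stats.mannwhitneyu(pooled_within, pooled_between,
                                         alternative="less")[1])
    frame.attrs["overall_p"] = overall_p
    frame.attrs["mean_within"] = float(np.mean(pooled_within))
    frame.attrs["mean_between"] = float(np.mean(pooled_between))
    return frame


def cv_analysis(mono: EventTable, multi: EventTable) -> pd.DataFrame:
    """Per-marker coefficient of variation, mono- vs multi-species pooling.

    CV = sample SD (n-1 divisor) / mean.  A marker with zero mean in
    either table is excluded with a warning.  The paired two-sided t-test
    across markers on (cv_mono - cv_multi) is stored in frame.attrs; by
    convention identical inputs give p = 1.
    """
    if mono.marker_names != multi.marker_names:
        raise ValueError("marker panels differ")
    rows = []
    for marker in mono.marker_names:
        x = mono.data[marker].to_numpy(dtype=float)
        y = multi.data[marker].to_numpy(dtype=float)
        if x.mean() == 0 or y.mean() == 0:
            logger.warning("marker %s has zero mean; CV undefined, excluded", marker)
            continue
        rows.append({
            "marker": marker,
            "cv_mono": float(x.std(ddof=1) / x.mean()),
            "cv_multi": float(y.std(ddof=1) / y.mean()),
        })
    frame = pd.DataFrame(rows)
    d = frame["cv_mono"] - frame["cv_multi"]
    if np.allclose(d, 0.0):
        p = 1.0
    else:
        p = float(stats.ttest_rel(frame["cv_mono"], frame["cv_multi"])[1])
    frame.attrs["t_test_p"] = p
    return frame


def reactivity_tests(table: EventTable, alpha: float = 0.05) -> pd.DataFrame:
    """Antibody reactivity and cross-species mean-level tests on pseudo-bulk.

    Per marker: one-sided one-sample t-test (H1: subject-level mean > 0)
    for non-zero reactivity; across species, one-way ANOVA on the subject
    means (pairwise two-sample t-tests when only two species), with
    Benjamini-Hochberg correction across markers.  A marker with zero
    variance and zero mean is reported as non-reactive (p = 1).
    """
    pb = (
        table.data.groupby(["species", "subject"], sort=True)[table.marker_names]
        .mean()
        .reset_index()
    )
    species_groups = {sp: g for sp, g in pb.groupby("species")}
    enough = (len(species_groups) >= 2
              and all(len(g) >= 2 for g in species_groups.values()))
    if len(species_groups) >= 2 and not enough:
        logger.warning("a species has < 2 subjects; ANOVA skipped")
    rows = []
    for marker in table.marker_names:
        vals = pb[marker].to_numpy(dtype=float)
        if np.allclose(vals.std(ddof=1) if len(vals) > 1 else 0.0, 0.0):
            p_react = 1.0 if np.allclose(vals.mean(), 0.0) else 0.0
        else:
            p_react = float(stats.ttest_1samp(vals, 0.0, alternative="greater")[1])
        row = {"marker": marker, "reactivity_p": p_react}
        if enough:
            groups = [g[marker].to_numpy(dtype=float) for g in species_groups.values()]
            if all(np.allclose(g, groups[0].mean()) for g in groups):
                row["species_anova_p"] = 1.0
            elif len(groups) == 2:
                row["species_anova_p"] = float(stats.ttest_ind(*groups)[1])
            else:
                row["species_anova_p"] = float(stats.f_oneway(*groups)[1])
        rows.append(row)
    frame = pd.DataFrame(rows)
    if "species_anova_p" in frame.columns:
        frame["species_anova_p_adj"] = multipletests(
            frame["species_anova_p"], method="fdr_bh"
        )[1]
    frame["reactive"] = frame["reactivity_p"] < alpha
    return frame


@dataclass
class ValidationReport:
    """Aggregate confounder report for one fitted model."""

    s_cluster: float
    s_species: float
    s_subject: float
    emd_within: float
    emd_between: float
    emd_pvalue: float
    cv_test_pvalue: float | None = None
    n_reactive_markers: int | None = None
    species_mean_anova_p: float | None = None
    per_marker: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=float)


def validation_report(table: EventTable, latent: np.ndarray, labels,
                      sample_n: int = 20000, seed: int = 0) -> ValidationReport:
    """Run the full battery against a fitted embedding + labeling."""
    s_cluster = silhouette_by_partition(latent, labels, sample_n, seed)
    s_species = silhouette_by_partition(latent, table.species.to_numpy(), sample_n, seed)
    s_subject = silhouette_by_partition(latent, table.subject.to_numpy(), sample_n, seed)
    emd = emd_within_between(table, labels, seed=seed)
    react = reactivity_tests(table)
    anova_p = (
        float(react["species_anova_p_adj"].min())
        if "species_anova_p_adj" in react.columns else None
    )
    return ValidationReport(
        s_cluster=s_cluster,
        s_species=s_species,
        s_subject=s_subject,
        emd_within=emd.attrs["mean_within"],
        emd_between=emd.attrs["mean_between"],
        emd_pvalue=emd.attrs["overall_p"],
        n_reactive_markers=int(react["reactive"].sum()),
        species_mean_anova_p=anova_p,
        per_marker={
            "emd": emd.to_dict(orient="list"),
            "reactivity": react.to_dict(orient="list"),
        },
    )
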