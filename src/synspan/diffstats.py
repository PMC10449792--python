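"""Differential statistics between species at cluster and pseudo-bulk level.

All tests use subjects — never single events — as the replication unit:
cluster abundances are per-subject event proportions, and expression
comparisons act on per-subject mean intensities (pseudo-bulk).  Low-
frequency (species, cluster) cells are filtered at a mean-frequency floor
before abundance testing; rank-sum p-values are exact for the small
subject counts typical of these designs and Benjamini-Hochberg corrected
within each analysis family.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .events import EventTable

logger = logging.getLogger(__name__)

#: Exact rank-sum distribution is used up to this per-group size.
EXACT_N = 12


@dataclass
class DiffConfig:
    freq_floor: float = 0.01
    alpha: float = 0.05
    fc_threshold: float = 0.5
    correction: str = "fdr_bh"

    def __post_init__(self) -> None:
        if not (0 <= self.freq_floor < 1):
            raise ValueError("freq_floor must be in [0, 1)")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class ClusterProfile:
    """Per-subject cluster composition and filtering state."""

    freq: pd.DataFrame              # subject x cluster proportions (unfiltered)
    counts: pd.DataFrame            # subject x cluster event counts
    species_of_subject: pd.Series   # subject -> species
    species_mean_freq: pd.DataFrame  # species x cluster mean of subject proportions
    retained: pd.DataFrame          # species x cluster bool (mean freq >= floor)
    freq_floor: float

    @property
    def clusters(self) -> list:
        return list(self.freq.columns)

    def species_specificity(self) -> pd.Series:
        """Which species survive the frequency floor in each cluster."""
        return self.retained.apply(lambda col: tuple(col.index[col]), axis=0)

    def filtered_freq(self) -> pd.DataFrame:
        """Subject x cluster proportions with filtered cells zeroed."""
        out = self.freq.copy()
        for cluster in out.columns:
            for sp in self.retained.index:
                if not self.retained.loc[sp, cluster]:
                    subj = self.species_of_subject[self.species_of_subject == sp].index
                    out.loc[out.index.intersection(subj), cluster] = 0.0
        return out


def cluster_frequencies(labels, metadata: pd.DataFrame,
                        cfg: DiffConfig | None = None) -> ClusterProfile:
    """Per-subject cluster proportions with the mean-frequency floor applied.

    ``metadata`` needs ``species`` and ``subject`` columns aligned with
    ``labels``.  A (species, cluster) cell whose mean subject proportion
    falls below ``cfg.freq_floor`` is marked filtered (noise floor).
    """
    cfg = cfg or DiffConfig()
    labels = np.asarray(labels)
    if len(labels) != len(metadata):
        raise ValueError("labels and metadata are not aligned")
    df = pd.DataFrame({
        "cluster": labels,
        "species": metadata["species"].to_numpy(),
        "subject": metadata["subject"].to_numpy(),
    })
    counts = df.groupby(["subject", "cluster"]).size().unstack(fill_value=0)
    if (counts.sum(axis=1) == 0).any():
        raise ValueError("subject with zero events")
    freq = counts.div(counts.sum(axis=1), axis=0)
    species_of_subject = (
        df.drop_duplicates("subject").set_index("subject")["species"].sort_index()
    )
    freq = freq.loc[species_of_subject.index]
    counts = counts.loc[species_of_subject.index]
    species_mean = freq.groupby(species_of_subject).mean()
    retained = species_mean >= cfg.freq_floor
    return ClusterProfile(
        freq=freq,
        counts=counts,
        species_of_subject=species_of_subject,
        species_mean_freq=species_mean,
        retained=retained,
        freq_floor=cfg.freq_floor,
    )


def _ranksum(x, y, alternative: str = "two-sided") -> float:
    """Exact Mann-Whitney/Wilcoxon rank-sum for small groups, else normal approx."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    method = "exact" if (len(x) <= EXACT_N and len(y) <= EXACT_N
                         and len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)
                         ) else "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative=alternative, method=method)[1])


def frequency_tests(profile: ClusterProfile, cfg: DiffConfig | None = None,
                    species_pair: tuple[str, str] | None = None) -> pd.DataFrame:
    """Species comparison of subject-level cluster abundances.

    Per cluster retained for both species: two-sided rank-sum on subject
    proportions, BH-corrected across clusters.  Clusters lacking either
    species (after the floor) are skipped.
    """
    cfg = cfg or DiffConfig()
    species = list(profile.species_mean_freq.index)
    if species_pair is None:
        if len(species) != 2:
            raise ValueError("species_pair required when not exactly 2 species")
        species_pair = (species[0], species[1])
    a, b = species_pair
    subj_a = profile.species_of_subject[profile.species_of_subject == a].index
    subj_b = profile.species_of_subject[profile.species_of_subject == b].index
    rows = []
    for cluster in profile.clusters:
        if not (profile.retained.loc[a, cluster] and profile.retained.loc[b, cluster]):
            continue
        fa = profile.freq.loc[subj_a, cluster].to_numpy()
        fb = profile.freq.loc[subj_b, cluster].to_numpy()
        if len(fa) < 2 or len(fb) < 2:
            logger.warning("cluster %s: < 2 subjects in a species; skipped", cluster)
            continue
        if np.array_equal(fa, fb) or (np.allclose(fa, fa.mean()) and np.allclose(fb, fb.mean()) and np.isclose(fa.mean(), fb.mean())):
            p = 1.0
        else:
            p = _ranksum(fa, fb)
        rows.append({
            "cluster": cluster,
            f"mean_{a}": float(fa.mean()),
            f"mean_{b}": float(fb.mean()),
            "p": p,
        })
    frame = pd.DataFrame(rows)
    if len(frame):
        frame["p_adj"] = benjamini_hochberg(frame["p"].to_numpy())
        frame["significant"] = frame["p_adj"] < cfg.alpha
    return frame


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values."""
    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]


def pseudobulk_table(table: EventTable, labels=None, cluster=None) -> pd.DataFrame:
    """Per-subject mean expression per marker (optionally within one cluster).

    Subjects are the replication unit for every downstream test; the
    returned frame is indexed by subject with a ``species`` column.
    """
    df = table.data
    if cluster is not None:
        if labels is None:
            raise ValueError("labels required to restrict to a cluster")
        df = df[np.asarray(labels) == cluster]
        if df.empty:
            raise ValueError(f"no events in cluster {cluster!r}")
    pb = df.groupby("subject", sort=True)[table.marker_names].mean()
    species = df.drop_duplicates("subject").set_index("subject")["species"]
    pb.insert(0, "species", species.loc[pb.index])
    return pb


def pseudobulk_differential(pb: pd.DataFrame, group_a, group_b,
                            consistency_pair: tuple | None = None,
                            cfg: DiffConfig | None = None,
                            extra_groups=None) -> pd.DataFrame:
    """Marker-level differential expression between two groups of subjects.

    `pb` is a subject x marker frame with a ``species`` column; `group_a`
    / `group_b` are species labels or lists thereof (e.g. primate =
    ["Hu", "NHP"]).  Per marker: two-sided rank-sum A vs B, BH across
    markers, effect = log2(meanA / meanB).  A "hit" needs adjusted
    p < alpha, |effect| > fc_threshold, and — when `consistency_pair` is
    given — no significant difference between that pair (raw p >= alpha).
    A Kruskal-Wallis p across A, B and `extra_groups` is attached per
    marker when extra groups are supplied.
    """
    cfg = cfg or DiffConfig()
    markers = [c for c in pb.columns if c != "species"]

    def rows_for(group):
        group = [group] if isinstance(group, str) else list(group)
        sel = pb[pb["species"].isin(group)]
        if len(sel) < 2:
            raise ValueError(f"group {group} has < 2 subjects")
        return sel

    A, B = rows_for(group_a), rows_for(group_b)
    cons = None
    if consistency_pair is not None:
        cons = (rows_for(consistency_pair[0]), rows_for(consistency_pair[1]))
    rows = []
    for marker in markers:
        xa = A[marker].to_numpy(dtype=float)
        xb = B[marker].to_numpy(dtype=float)
        p = 1.0 if np.array_equal(np.sort(xa), np.sort(xb)) else _ranksum(xa, xb)
        ma, mb = xa.mean(), xb.mean()
        if ma > 0 and mb > 0:
            effect, effect_kind = float(np.log2(ma / mb)), "log2fc"
        else:
            effect, effect_kind = float(ma - mb), "difference"
        row = {
            "marker": marker, "mean_a": float(ma), "mean_b": float(mb),
            "p": p, "effect": effect, "effect_kind": effect_kind,
        }
        if cons is not None:
            ca = cons[0][marker].to_numpy(dtype=float)
            cb = cons[1][marker].to_numpy(dtype=float)
            row["consistency_p"] = (1.0 if np.array_equal(np.sort(ca), np.sort(cb))
                                    else _ranksum(ca, cb))
        if extra_groups:
            groups = [xa, xb] + [rows_for(g)[marker].to_numpy(dtype=float)
                                 for g in extra_groups]
            if all(np.allclose(g, groups[0].mean()) for g in groups):
                row["kruskal_p"] = 1.0
            else:
                row["kruskal_p"] = float(stats.kruskal(*groups)[1])
        rows.append(row)
    frame = pd.DataFrame(rows)
    frame["p_adj"] = benjamini_hochberg(frame["p"].to_numpy())
    hit = (frame["p_adj"] < cfg.alpha) & (frame["effect"].abs() > cfg.fc_threshold)
    if cons is not None:
        hit &= frame["consistency_p"] >= cfg.alpha
    frame["hit"] = hit
    return frame


def per_cluster_differential(table: EventTable, labels, species_a: str,
                             species_b: str,
                             cfg: DiffConfig | None = None) -> pd.DataFrame:
    """Within-cluster, per-marker differential expression between two species.

    Uses subject-level means within each retained cluster; BH is applied
    jointly across every tested (cluster, marker) pair.  Clusters lacking
    >= 2 subjects of either species are skipped.
    """
    cfg = cfg or DiffConfig()
    labels = np.asarray(labels)
    profile = cluster_frequencies(labels, table.data, cfg)
    rows = []
    for cluster in profile.clusters:
        ok_a = species_a in profile.retained.index and profile.retained.loc[species_a, cluster]
        ok_b = species_b in profile.retained.index and profile.retained.loc[species_b, cluster]
        if not (ok_a and ok_b):
            continue
        sub = table.data[labels == cluster]
        pb = sub.groupby("subject", sort=True)[table.marker_names].mean()
        sp = sub.drop_duplicates("subject").set_index("subject")["species"]
        A = pb[sp.loc[pb.index] == species_a]
        B = pb[sp.loc[pb.index] == species_b]
        if len(A) < 2 or len(B) < 2:
            logger.warning("cluster %s: < 2 subjects per species; skipped", cluster)
            continue
        for marker in table.marker_names:
            xa, xb = A[marker].to_numpy(), B[marker].to_numpy()
            p = 1.0 if np.array_equal(np.sort(xa), np.sort(xb)) else _ranksum(xa, xb)
            ma, mb = xa.mean(), xb.mean()
            if ma > 0 and mb > 0:
                effect, kind = float(np.log2(ma / mb)), "log2fc"
            else:
                effect, kind = float(ma - mb), "difference"
            rows.append({"cluster": cluster, "marker": marker, "p": p,
                         "effect": effect, "effect_kind": kind})
    frame = pd.DataFrame(rows)
    if len(frame):
        frame["p_adj"] = benjamini_hochberg(frame["p"].to_numpy())
        frame["hit"] = (frame["p_adj"] < cfg.alpha) & (frame["effect"].abs() > cfg.fc_threshold)
    return frame
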