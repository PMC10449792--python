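"""End-to-end region-level analysis driven by a manifest.

One model per brain region (events from several regions are never
pooled; regional variability would otherwise confound the clustering).
The pipeline chains: load -> arcsinh -> species balancing -> K selection
-> seeded run ensemble -> consensus -> confounder validation -> cluster
frequencies and differential statistics -> graphs, and writes all
artifacts plus a machine-readable JSON summary.  All randomness descends
deterministically from the manifest's base seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .dec import SynTofDEC, TrainConfig
from .diffstats import (DiffConfig, cluster_frequencies, frequency_tests,
                        pseudobulk_differential, pseudobulk_table)
from .events import (DEFAULT_COFACTOR, EventTable, arcsinh_transform,
                     balanced_downsample, load_events)
from .graphs import correlation_graph, fr_layout, species_cluster_profiles
from .validate import validation_report

logger = logging.getLogger(__name__)


@dataclass
class RunManifest:
    """Everything needed to reproduce one region-level analysis."""

    region: str
    output_dir: str
    input_path: str | None = None      # CSV/Parquet event table
    input_regions: list[str] | None = None  # regions present in the input file
    k: int | str = "auto"
    k_range: tuple[int, int] = (8, 25)
    per_species: int | None = None     # balanced events per species; None = min
    cofactor: float = DEFAULT_COFACTOR
    seed: int = 0
    train: TrainConfig = field(default_factory=TrainConfig)
    diff: DiffConfig = field(default_factory=DiffConfig)

    def __post_init__(self) -> None:
        if self.input_regions is not None and len(set(self.input_regions)) > 1:
            raise ValueError(
                "a manifest covers exactly one brain region; "
                f"got {sorted(set(self.input_regions))}"
            )


def _check_single_region(table: EventTable, region: str) -> EventTable:
    if "region" in table.data.columns:
        present = set(table.data["region"].unique())
        if len(present) > 1:
            raise ValueError(f"input pools multiple regions {sorted(present)}; "
                             "one model per region")
        if present and region not in present:
            raise ValueError(f"manifest region {region!r} not in input {present}")
    return table


def run_pipeline(manifest: RunManifest, table: EventTable | None = None) -> dict:
    """Execute the full analysis; returns the JSON-ready summary dict.

    `table` may be passed directly (e.g. fresh synthetic data); otherwise
    it is loaded from ``manifest.input_path``.
    """
    t0 = time.time()
    out = Path(manifest.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "region": manifest.region,
        "seed": manifest.seed,
        "version": __version__,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "manifest": _manifest_dict(manifest),
        "stages": {},
    }

    def stage(name):
        logger.info("stage: %s", name)
        summary["stages"][name] = round(time.time() - t0, 2)

    try:
        stage("load")
        if table is None:
            if manifest.input_path is None:
                raise ValueError("manifest has no input_path and no table was given")
            table = load_events(manifest.input_path)
        table = _check_single_region(table, manifest.region)

        stage("transform")
        transformed = arcsinh_transform(table, manifest.cofactor)

        stage("balance")
        counts = transformed.species.value_counts()
        per_species = manifest.per_species or int(counts.min())
        balanced = balanced_downsample(transformed, per_species, seed=manifest.seed)
        summary["n_events_input"] = int(table.n_events)
        summary["n_events_balanced"] = int(balanced.n_events)

        stage("fit")
        model = SynTofDEC(balanced, manifest.train)
        res = model.fit(k=manifest.k, seed=manifest.seed,
                        k_range=range(*manifest.k_range))
        summary["k"] = res.k
        summary["n_clusters"] = res.n_clusters
        summary["mean_fscore"] = res.consensus.mean_fscore
        summary["mean_nmi"] = res.consensus.mean_nmi
        if res.k_selection is not None:
            summary["elbow"] = {
                "k": res.k_selection.k,
                "strength": round(res.k_selection.strength, 4),
                "has_elbow": res.k_selection.has_elbow,
                "sse": [round(s, 2) for s in res.k_selection.sse],
            }
        labeled = balanced.data.copy()
        labeled["cluster"] = res.labels
        labeled.to_csv(out / "events_labeled.csv", index=False, float_format="%.6g")
        with open(out / "training_summary.txt", "w") as fh:
            fh.write(res.summary() + "\n")

        stage("validate")
        report = validation_report(balanced, res.latent, res.labels,
                                   seed=manifest.seed)
        report.to_json(out / "validation_report.json")
        summary["validation"] = {
            "s_cluster": report.s_cluster,
            "s_species": report.s_species,
            "s_subject": report.s_subject,
            "emd_within": report.emd_within,
            "emd_between": report.emd_between,
            "emd_pvalue": report.emd_pvalue,
        }

        stage("frequencies")
        profile = cluster_frequencies(res.labels, balanced.data, manifest.diff)
        profile.freq.to_csv(out / "cluster_frequencies.csv", float_format="%.6g")
        profile.species_mean_freq.to_csv(out / "species_mean_frequencies.csv",
                                         float_format="%.6g")
        species = list(profile.species_mean_freq.index)
        freq_results = {}
        for i in range(len(species)):
            for j in range(i + 1, len(species)):
                pair = (species[i], species[j])
                ft = frequency_tests(profile, manifest.diff, species_pair=pair)
                if len(ft):
                    ft.to_csv(out / f"frequency_tests_{pair[0]}_vs_{pair[1]}.csv",
                              index=False, float_format="%.6g")
                freq_results["_vs_".join(pair)] = int(ft["significant"].sum()) if len(ft) else 0
        summary["frequency_hits"] = freq_results
        summary["species_specificity"] = {
            str(c): list(map(str, sps))
            for c, sps in profile.species_specificity().items()
        }

        stage("pseudobulk")
        pb = pseudobulk_table(balanced)
        pb.to_csv(out / "pseudobulk.csv", float_format="%.6g")
        if len(species) >= 2:
            diff = pseudobulk_differential(pb, species[0], species[1],
                                           cfg=manifest.diff)
            diff.to_csv(out / f"pseudobulk_{species[0]}_vs_{species[1]}.csv",
                        index=False, float_format="%.6g")
            summary["pseudobulk_hits"] = int(diff["hit"].sum())

        stage("graphs")
        profiles = species_cluster_profiles(balanced, res.labels)
        corr = correlation_graph(profiles, alpha=manifest.diff.alpha)
        fr_layout(corr, seed=manifest.seed)
        corr.edge_table_csv(out / "correlation_edges.csv")
        corr.to_json(out / "correlation_graph.json")
        summary["correlation_edges_retained"] = int(corr.edges["retained"].sum())

        summary["runtime_s"] = round(time.time() - t0, 2)
        summary["status"] = "ok"
    except Exception as exc:
        summary["status"] = "failed"
        summary["error"] = f"{type(exc).__name__}: {exc}"
        summary["failed_stage"] = list(summary["stages"])[-1] if summary["stages"] else None
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=1, default=_json_default)
        raise

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, default=_json_default)
    return summary


def _manifest_dict(manifest: RunManifest) -> dict:
    d = dataclasses.asdict(manifest)
    return d


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)
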