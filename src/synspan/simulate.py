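"""Synthetic SynTOF-like multi-species event data with planted ground truth.

The generator emulates the structure of a three-species cerebral-cortex
single-presynapse experiment: a 20-antibody panel, unequal subject and
event counts per species, ~16 latent presynaptic subpopulations of which
11 are shared by the two primate species only, 4 are mouse-exclusive, and
one low-expression subpopulation is shared by all species (events the
panel cannot distinguish).  Raw intensities are right-skewed and
nonnegative (log-normal around each subpopulation's mean); per-subject
batch shifts and measurement noise act additively on the arcsinh scale.
Truth labels ride along in a reserved metadata column so recovery can be
scored without a side file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .events import DEFAULT_COFACTOR, EventTable

#: The 20-marker presynaptic panel (cross-species reactive antibodies).
PANEL_20 = [
    "CD47", "CD56", "GAD65", "VGLUT", "VMAT2", "SERT", "NET",
    "ApoE", "AS", "APP", "BIN1", "Calreticulin", "DJ1", "GAMT",
    "GATM", "LRRK2", "Parkin", "SLC6A8", "Synaptobrevin2", "TMEM230",
]


@dataclass
class ClusterSpec:
    """One planted presynaptic subpopulation."""

    name: str
    species: tuple[str, ...]            # member species
    mean: np.ndarray                    # per-marker raw-scale mean, >= 0
    dispersion: np.ndarray              # per-marker log-normal sigma, >= 0
    weight: dict[str, float]            # expected mixing weight per member species

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.dispersion = np.broadcast_to(
            np.asarray(self.dispersion, dtype=float), self.mean.shape
        ).copy()
        if (self.mean < 0).any():
            raise ValueError(f"cluster {self.name}: negative mean")
        if (self.dispersion < 0).any():
            raise ValueError(f"cluster {self.name}: negative dispersion")
        missing = [s for s in self.species if s not in self.weight]
        if missing:
            raise ValueError(f"cluster {self.name}: no weight for {missing}")


@dataclass
class SynthConfig:
    """Full description of a synthetic multi-species experiment."""

    species_names: list[str]
    subjects_per_species: dict[str, int]
    events_per_subject: int
    cluster_specs: list[ClusterSpec]
    marker_names: list[str] = field(default_factory=lambda: list(PANEL_20))
    subject_effect_sd: float = 0.05
    noise_sd: float = 0.05
    region: str = "CTX"
    females_per_species: dict[str, int] | None = None
    cofactor: float = DEFAULT_COFACTOR
    seed: int = 0

    @property
    def n_species(self) -> int:
        return len(self.species_names)

    @property
    def n_markers(self) -> int:
        return len(self.marker_names)

    def validate(self) -> None:
        if self.subject_effect_sd < 0 or self.noise_sd < 0:
            raise ValueError("effect/noise SDs must be nonnegative")
        if self.events_per_subject < 1:
            raise ValueError("events_per_subject must be >= 1")
        if self.n_markers < 1:
            raise ValueError("need at least one marker")
        for spec in self.cluster_specs:
            if spec.mean.shape != (self.n_markers,):
                raise ValueError(f"cluster {spec.name}: mean has wrong length")
            unknown = [s for s in spec.species if s not in self.species_names]
            if unknown:
                raise ValueError(f"cluster {spec.name}: unknown species {unknown}")
        for sp in self.species_names:
            w = self.mixing_weights(sp)
            if not w:
                raise ValueError(f"species {sp} belongs to no cluster")
            total = sum(w.values())
            if abs(total - 1.0) > 1e-8:
                raise ValueError(f"species {sp}: mixing weights sum to {total}, not 1")

    def mixing_weights(self, species: str) -> dict[str, float]:
        """Cluster-name -> mixing weight for one species."""
        return {
            spec.name: spec.weight[species]
            for spec in self.cluster_specs
            if species in spec.species
        }

    # -- serialisation -----------------------------------------------------
    def to_json(self, path) -> None:
        payload = asdict(self)
        for spec in payload["cluster_specs"]:
            spec["mean"] = list(map(float, spec["mean"]))
            spec["dispersion"] = list(map(float, spec["dispersion"]))
            spec["species"] = list(spec["species"])
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SynthConfig":
        with open(path) as fh:
            payload = json.load(fh)
        payload["cluster_specs"] = [
            ClusterSpec(
                name=s["name"],
                species=tuple(s["species"]),
                mean=np.asarray(s["mean"]),
                dispersion=np.asarray(s["dispersion"]),
                weight=s["weight"],
            )
            for s in payload["cluster_specs"]
        ]
        return cls(**payload)


def default_cortex_scenario(
    events_per_subject: int = 3333,
    subject_effect_sd: float = 0.05,
    noise_sd: float = 0.05,
    dispersion: float = 0.25,
    seed: int = 0,
) -> SynthConfig:
    """Three-species cerebral-cortex scenario with 16 planted subpopulations.

    Composition mirrors the cross-species cortical landscape: 11 clusters
    shared by the two primate species only (P1-P11), 4 mouse-exclusive
    clusters (Mu1-Mu4), and one all-species low-expression cluster (A1)
    that absorbs events the panel cannot distinguish (a larger share of
    mouse events than primate events).  Two designated clusters (P8, Mu4)
    co-express VGLUT and GAD65, and P4 is a "high-expressed" cluster with
    elevated means on most markers.  Subject counts: Hu 6 (2 F), NHP 4
    (4 F), Mu 5 (3 F).
    """
    rng = np.random.default_rng(20)  # scenario geometry is fixed, not a dial
    markers = list(PANEL_20)
    n_markers = len(markers)
    base = 0.5       # raw-scale background intensity
    hi_lo, hi_span = 25.0, 50.0  # elevated means drawn in [25, 75]

    primates = ("Hu", "NHP")
    names = [f"P{i}" for i in range(1, 12)] + [f"Mu{i}" for i in range(1, 5)]
    member: dict[str, tuple[str, ...]] = {n: primates for n in names[:11]}
    member.update({n: ("Mu",) for n in names[11:]})

    idx = {m: i for i, m in enumerate(markers)}
    means: dict[str, np.ndarray] = {}
    n_signature = 6
    signatures: list[frozenset[int]] = []
    for name in names:
        # rejection-sample signatures so any two clusters differ in >= 4 markers
        while True:
            sig = frozenset(rng.choice(n_markers, size=n_signature, replace=False))
            if all(len(sig ^ prev) >= 8 for prev in signatures):
                break
        signatures.append(sig)
        mean = np.full(n_markers, base)
        mean[sorted(sig)] = hi_lo + hi_span * rng.random(n_signature)
        means[name] = mean
    # biology-flavoured constraints
    for name in ("P8", "Mu4"):  # VGLUT+GAD65 co-expressing cluster per lineage
        means[name][idx["VGLUT"]] = 60.0
        means[name][idx["GAD65"]] = 55.0
    high = means["P4"]          # "high-expressed" cluster: most markers elevated
    high[:] = hi_lo + hi_span * rng.random(n_markers)
    high[idx["VGLUT"]], high[idx["VMAT2"]], high[idx["SERT"]] = 70.0, 65.0, 60.0

    specs: list[ClusterSpec] = []
    # uneven primate weights over P1..P11 (3% reserved for A1), Mu over Mu1-4 (30% A1)
    prim_raw = 0.5 + rng.random(11)
    prim_w = 0.97 * prim_raw / prim_raw.sum()
    mu_raw = 0.5 + rng.random(4)
    mu_w = 0.70 * mu_raw / mu_raw.sum()
    for j, name in enumerate(names[:11]):
        specs.append(
            ClusterSpec(
                name=name, species=primates, mean=means[name],
                dispersion=np.full(n_markers, dispersion),
                weight={"Hu": float(prim_w[j]), "NHP": float(prim_w[j])},
            )
        )
    for j, name in enumerate(names[11:]):
        specs.append(
            ClusterSpec(
                name=name, species=("Mu",), mean=means[name],
                dispersion=np.full(n_markers, dispersion),
                weight={"Mu": float(mu_w[j])},
            )
        )
    specs.append(
        ClusterSpec(
            name="A1", species=("Hu", "NHP", "Mu"),
            mean=np.full(n_markers, 0.05),
            dispersion=np.full(n_markers, dispersion),
            weight={"Hu": 0.03, "NHP": 0.03, "Mu": 0.30},
        )
    )

    config = SynthConfig(
        species_names=["Hu", "NHP", "Mu"],
        subjects_per_species={"Hu": 6, "NHP": 4, "Mu": 5},
        events_per_subject=events_per_subject,
        cluster_specs=specs,
        marker_names=markers,
        subject_effect_sd=subject_effect_sd,
        noise_sd=noise_sd,
        region="CTX",
        females_per_species={"Hu": 2, "NHP": 4, "Mu": 3},
        seed=seed,
    )
    config.validate()
    return config


def generate_events(config: SynthConfig, seed: int | None = None) -> EventTable:
    """Draw a fully labelled synthetic :class:`EventTable` from `config`.

    Per subject: cluster memberships are multinomial draws from the
    species' mixing weights; raw marker intensities are log-normal around
    the cluster mean (``exp(N(log mean, dispersion))``, exactly the mean
    when dispersion is 0); the subject's batch shift and event-level noise
    are added on the arcsinh scale and mapped back, clipping at zero to
    keep intensities nonnegative.  Deterministic for a fixed seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    cof = config.cofactor
    spec_by_name = {s.name: s for s in config.cluster_specs}
    frames: list[pd.DataFrame] = []
    for sp in config.species_names:
        weights = config.mixing_weights(sp)
        cluster_names = list(weights)
        probs = np.array([weights[c] for c in cluster_names])
        n_subjects = config.subjects_per_species[sp]
        n_females = (config.females_per_species or {}).get(sp, 0)
        for s_idx in range(n_subjects):
            subject_id = f"{sp}{s_idx + 1}"
            sex = "F" if s_idx < n_females else "M"
            shift = rng.normal(0.0, config.subject_effect_sd) if config.subject_effect_sd > 0 else 0.0
            n = config.events_per_subject
            assignment = rng.choice(len(cluster_names), size=n, p=probs)
            raw = np.empty((n, config.n_markers))
            for c_idx, c_name in enumerate(cluster_names):
                mask = assignment == c_idx
                if not mask.any():
                    continue
                spec = spec_by_name[c_name]
                with np.errstate(divide="ignore"):
                    log_mean = np.log(np.maximum(spec.mean, 1e-12))
                draws = rng.normal(
                    log_mean, spec.dispersion, size=(int(mask.sum()), config.n_markers)
                )
                block = np.exp(draws)
                block[:, spec.mean == 0] = 0.0
                raw[mask] = block
            y = np.arcsinh(raw / cof) + shift
            if config.noise_sd > 0:
                y = y + rng.normal(0.0, config.noise_sd, size=y.shape)
            raw_out = np.maximum(np.sinh(y) * cof, 0.0)
            df = pd.DataFrame(raw_out, columns=config.marker_names)
            df["species"] = sp
            df["subject"] = subject_id
            df["region"] = config.region
            df["sex"] = sex
            df["truth"] = [cluster_names[a] for a in assignment]
            frames.append(df)
    table = pd.concat(frames, ignore_index=True)
    return EventTable(table)
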