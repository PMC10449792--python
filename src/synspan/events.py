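"""Single-event expression tables: loading, arcsinh transform, species balancing.

A SynTOF acquisition yields one row per gated presynaptic event and one
column per antibody channel.  :class:`EventTable` wraps that matrix as a
pandas DataFrame together with per-event metadata (species, subject, brain
region, sex, and optionally a planted ground-truth label for synthetic
data).  Metadata live in reserved columns so a table round-trips through a
single CSV/Parquet file.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Reserved (non-marker) column names, in canonical order.  ``truth``
#: carries planted ground-truth labels, ``cluster`` fitted labels.
METADATA_COLUMNS = ("species", "subject", "region", "sex", "truth", "cluster")

#: Default arcsinh cofactor (CyTOF convention).
DEFAULT_COFACTOR = 5.0

#: FCS channels that are never panel markers.
NON_MARKER_CHANNELS = frozenset(
    {"Time", "time", "Event_length", "EventLength", "Center", "Offset",
     "Width", "Residual", "beadDist"}
)


@dataclass
class EventTable:
    """Events x markers intensity matrix plus per-event metadata.

    Parameters
    ----------
    data : pandas.DataFrame
        One row per event.  Marker columns are every column not listed in
        :data:`METADATA_COLUMNS`; ``species`` and ``subject`` are required.
    """

    data: pd.DataFrame
    marker_names: list[str] = field(init=False)

    def __post_init__(self) -> None:
        cols = list(self.data.columns)
        self.marker_names = [c for c in cols if c not in METADATA_COLUMNS]
        if not self.marker_names:
            raise ValueError("EventTable has no marker columns")
        if len(self.data) == 0:
            raise ValueError("EventTable has no events")
        if len(set(self.marker_names)) != len(self.marker_names):
            raise ValueError("duplicate marker names")
        for required in ("species", "subject"):
            if required not in cols:
                raise ValueError(f"missing required metadata column {required!r}")
            if self.data[required].isna().any():
                raise ValueError(f"events with missing {required!r} metadata")
        x = self.data[self.marker_names].to_numpy()
        if not np.isfinite(x).all():
            raise ValueError("non-finite marker intensities")

    # -- accessors ---------------------------------------------------------
    @property
    def intensities(self) -> np.ndarray:
        """Events x markers float array (a copy)."""
        return self.data[self.marker_names].to_numpy(dtype=float)

    @property
    def species(self) -> pd.Series:
        return self.data["species"]

    @property
    def subject(self) -> pd.Series:
        return self.data["subject"]

    @property
    def truth(self) -> pd.Series | None:
        return self.data["truth"] if "truth" in self.data.columns else None

    @property
    def n_events(self) -> int:
        return len(self.data)

    @property
    def n_markers(self) -> int:
        return len(self.marker_names)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return len(self.data)

    # -- construction / IO -------------------------------------------------
    @classmethod
    def from_arrays(
        cls,
        intensities: np.ndarray,
        marker_names: list[str],
        species,
        subject,
        region=None,
        sex=None,
        truth=None,
    ) -> "EventTable":
        intensities = np.asarray(intensities, dtype=float)
        df = pd.DataFrame(intensities, columns=list(marker_names))
        df["species"] = np.asarray(species)
        df["subject"] = np.asarray(subject)
        if region is not None:
            df["region"] = np.asarray(region)
        if sex is not None:
            df["sex"] = np.asarray(sex)
        if truth is not None:
            df["truth"] = np.asarray(truth)
        return cls(df)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    def to_parquet(self, path) -> None:
        self.data.to_parquet(path, index=False)

    def copy_with(self, intensities: np.ndarray) -> "EventTable":
        """New table with replaced intensities, metadata untouched."""
        df = self.data.copy()
        df[self.marker_names] = np.asarray(intensities, dtype=float)
        return EventTable(df)


def load_events(
    path,
    format: str | None = None,
    metadata_map: dict | None = None,
    markers: list[str] | None = None,
) -> EventTable:
    """Load an :class:`EventTable` from CSV, Parquet, or FCS.

    Parameters
    ----------
    format : {"csv", "parquet", "fcs"}, optional
        Inferred from the file suffix when omitted.
    metadata_map : dict, optional
        Required for FCS.  Maps each metadata field (``species``,
        ``subject``, optionally ``region``/``sex``) either to a literal
        value or to ``"$KEYWORD"``, a reference to an FCS TEXT keyword.
    markers : list of str, optional
        Panel marker names.  For FCS, channels outside the panel are
        dropped; a panel marker absent from the file is an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        suffix = path.suffix.lower().lstrip(".")
        format = {"csv": "csv", "parquet": "parquet", "pq": "parquet", "fcs": "fcs"}.get(suffix)
        if format is None:
            raise ValueError(f"cannot infer format from suffix {path.suffix!r}")
    if format == "csv":
        df = pd.read_csv(path)
    elif format == "parquet":
        df = pd.read_parquet(path)
    elif format == "fcs":
        from .fcs import read_fcs

        channel_names, matrix, keywords = read_fcs(path)
        keep = []
        for i, name in enumerate(channel_names):
            if markers is not None:
                if name in markers:
                    keep.append(i)
            elif name not in NON_MARKER_CHANNELS:
                keep.append(i)
        if markers is not None:
            present = {channel_names[i] for i in keep}
            missing = [m for m in markers if m not in present]
            if missing:
                raise ValueError(f"panel markers absent from FCS file: {missing}")
        df = pd.DataFrame(matrix[:, keep], columns=[channel_names[i] for i in keep])
        if metadata_map is None:
            raise ValueError("metadata_map is required for FCS input")
        for key, value in metadata_map.items():
            if isinstance(value, str) and value.startswith("$"):
                # "$NAME" references the TEXT keyword NAME (or $NAME itself)
                resolved = keywords.get(value, keywords.get(value[1:]))
                if resolved is None:
                    raise ValueError(f"FCS keyword {value!r} not present")
                df[key] = resolved
            else:
                df[key] = value
    else:
        raise ValueError(f"unknown format {format!r}")
    return EventTable(df)


def arcsinh_transform(table: EventTable, cofactor: float = DEFAULT_COFACTOR) -> EventTable:
    """Variance-stabilising transform ``asinh(x / cofactor)`` per intensity.

    Strictly monotone per marker; metadata untouched.
    """
    if cofactor <= 0:
        raise ValueError("cofactor must be positive")
    return table.copy_with(np.arcsinh(table.intensities / cofactor))


def balanced_downsample(table: EventTable, per_species: int, seed: int) -> EventTable:
    """Species-balanced downsampling, stratified over each species' subjects.

    Each species contributes ``min(per_species, available)`` events drawn
    without replacement.  Within a species the quota is split across
    subjects proportionally to their event counts (largest-remainder
    rounding) so that no subject dominates the balanced set.
    """
    if per_species < 1:
        raise ValueError("per_species must be >= 1")
    rng = np.random.default_rng(seed)
    keep_indices: list[np.ndarray] = []
    for sp, sp_df in table.data.groupby("species", sort=True):
        available = len(sp_df)
        target = min(per_species, available)
        if target < per_species:
            logger.warning(
                "species %s has only %d events (< %d requested); keeping all",
                sp, available, per_species,
            )
            warnings.warn(
                f"species {sp}: only {available} events available, keeping all",
                stacklevel=2,
            )
        counts = sp_df.groupby("subject", sort=True).size()
        quota = _proportional_allocation(counts.to_numpy(), target)
        for (subj, n_take) in zip(counts.index, quota):
            idx = sp_df.index[sp_df["subject"] == subj].to_numpy()
            take = rng.choice(idx, size=n_take, replace=False)
            keep_indices.append(np.sort(take))
    keep = np.concatenate(keep_indices)
    keep.sort()
    return EventTable(table.data.loc[keep].reset_index(drop=True))


def _proportional_allocation(counts: np.ndarray, total: int) -> np.ndarray:
    """Largest-remainder allocation of `total` over strata of size `counts`."""
    counts = np.asarray(counts, dtype=int)
    if total >= counts.sum():
        return counts.copy()
    exact = counts * (total / counts.sum())
    alloc = np.floor(exact).astype(int)
    # never allocate more than available
    alloc = np.minimum(alloc, counts)
    remainder = exact - alloc
    shortfall = total - alloc.sum()
    order = np.argsort(-remainder, kind="stable")
    for i in order:
        if shortfall == 0:
            break
        if alloc[i] < counts[i]:
            alloc[i] += 1
            shortfall -= 1
    # pathological rounding: distribute any rest wherever room remains
    while shortfall > 0:
        for i in np.argsort(alloc - counts):
            if alloc[i] < counts[i]:
                alloc[i] += 1
                shortfall -= 1
                break
    return alloc
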