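"""Parcel-to-network assignment.

A parcellation maps every parcel (graph node) to exactly one of K
functional networks. The reference scheme is the 12-network
Cole-Anticevic Brain Network Parcellation (CAB-NP); the desk-scale
default used throughout the test-suite keeps the 12 CAB-NP network
names but assigns far fewer parcels (60 by default, 5 per network).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

#: The 12 CAB-NP network names, in their conventional order.
CABNP_NETWORKS = (
    "Primary Visual",
    "Secondary Visual",
    "Somatomotor",
    "Cingulo-Opercular",
    "Dorsal Attention",
    "Language",
    "Frontoparietal",
    "Auditory",
    "Default Mode",
    "Posterior Multimodal",
    "Ventral Multimodal",
    "Orbito-Affective",
)


@dataclass(frozen=True)
class Parcellation:
    """Ordered parcels with a fixed community (network) assignment.

    Parameters
    ----------
    parcel_ids
        Ordered parcel identifiers; defines node order for every matrix
        in the pipeline.
    network_index
        Zero-based network index per parcel, aligned with ``parcel_ids``.
    network_names
        Names of the K networks.
    """

    parcel_ids: tuple[str, ...]
    network_index: tuple[int, ...]
    network_names: tuple[str, ...] = field(default=CABNP_NETWORKS)

    def __post_init__(self) -> None:
        if len(self.parcel_ids) != len(self.network_index):
            raise ValueError("parcel_ids and network_index lengths differ")
        k = len(self.network_names)
        for i in self.network_index:
            if not 0 <= i < k:
                raise ValueError(f"network index {i} outside [0, {k})")

    @property
    def n_parcels(self) -> int:
        return len(self.parcel_ids)

    @property
    def n_networks(self) -> int:
        return len(self.network_names)

    @property
    def labels(self) -> np.ndarray:
        """Zero-based network index per parcel as an int array."""
        return np.asarray(self.network_index, dtype=np.intp)

    def members(self, network: int | str) -> np.ndarray:
        """Indices of the parcels assigned to a network."""
        if isinstance(network, str):
            network = self.network_names.index(network)
        return np.flatnonzero(self.labels == network)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parcel_id": self.parcel_ids,
                "parcel_name": self.parcel_ids,
                "network_index": [i + 1 for i in self.network_index],
                "network_name": [self.network_names[i] for i in self.network_index],
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def load_parcellation(path: str | Path) -> Parcellation:
    """Read a parcellation table (TSV: parcel_id, parcel_name,
    network_index 1..K, network_name)."""
    df = pd.read_csv(path, sep="\t")
    required = {"parcel_id", "network_index", "network_name"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"parcellation file missing columns: {sorted(missing)}")
    # network_names ordered by their 1-based index
    pairs = (
        df[["network_index", "network_name"]]
        .drop_duplicates()
        .sort_values("network_index")
    )
    idx = pairs["network_index"].to_numpy()
    if not np.array_equal(idx, np.arange(1, len(idx) + 1)):
        raise ValueError("network_index values must be contiguous from 1")
    return Parcellation(
        parcel_ids=tuple(str(p) for p in df["parcel_id"]),
        network_index=tuple(int(i) - 1 for i in df["network_index"]),
        network_names=tuple(str(n) for n in pairs["network_name"]),
    )


def default_parcellation(n_parcels: int = 60, n_networks: int = 12) -> Parcellation:
    """Desk-scale stand-in for CAB-NP: ``n_parcels`` parcels split as
    evenly as possible over ``n_networks`` networks (CAB-NP names when
    K=12), contiguous blocks in parcel order."""
    if n_networks < 2:
        raise ValueError("need at least 2 networks")
    if n_parcels < n_networks:
        raise ValueError("need at least one parcel per network")
    if n_networks == 12:
        names = CABNP_NETWORKS
    else:
        names = tuple(f"Network{i + 1:02d}" for i in range(n_networks))
    sizes = np.full(n_networks, n_parcels // n_networks, dtype=int)
    sizes[: n_parcels % n_networks] += 1
    index = tuple(int(i) for i in np.repeat(np.arange(n_networks), sizes))
    ids = tuple(f"P{i + 1:03d}" for i in range(n_parcels))
    return Parcellation(parcel_ids=ids, network_index=index, network_names=names)


def bundled_parcellation() -> Parcellation:
    """The packaged 60-parcel, 12-network fixture table."""
    with resources.as_file(
        resources.files("fcgraph").joinpath("data/cabnp_desk60.tsv")
    ) as p:
        return load_parcellation(p)
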