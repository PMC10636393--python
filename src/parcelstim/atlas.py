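"""Parcel atlas bookkeeping.

The atlas is consumed as a table: one row per parcel with its name,
hemisphere, anatomical location, large-scale network membership, depth below
the scalp surface (mm) and a centroid in head coordinates (mm). Surface
geometry itself is never touched; depth is an attribute supplied by the
atlas (here, by the synthetic geometry generator).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Canonical large-scale network labels used throughout the package.
NETWORKS = ("DMN", "CEN", "Salience", "Other")

ATLAS_COLUMNS = [
    "parcel_id",
    "name",
    "hemisphere",
    "location",
    "network",
    "depth_mm",
    "x",
    "y",
    "z",
    "subcortical",
]


class ParcelAtlas:
    """Table of parcels: identity, network membership and scalp depth.

    Parameters
    ----------
    table : pandas.DataFrame
        Must contain :data:`ATLAS_COLUMNS` (``subcortical`` defaults to
        False when absent). ``parcel_id`` values must be unique.
    """

    def __init__(self, table: pd.DataFrame):
        table = table.copy()
        if "subcortical" not in table.columns:
            table["subcortical"] = False
        missing = [c for c in ATLAS_COLUMNS if c not in table.columns]
        if missing:
            raise ValueError(f"atlas table missing columns: {missing}")
        if table["parcel_id"].duplicated().any():
            dupes = table.loc[table["parcel_id"].duplicated(), "parcel_id"]
            raise ValueError(f"duplicate parcel_ids: {sorted(set(dupes))}")
        if (table["depth_mm"] < 0).any():
            raise ValueError("parcel depths must be nonnegative")
        self.table = table[ATLAS_COLUMNS].reset_index(drop=True)

    @property
    def n_parcels(self) -> int:
        return len(self.table)

    @property
    def parcel_ids(self) -> list:
        return list(self.table["parcel_id"])

    @property
    def networks(self) -> pd.Series:
        return self.table["network"]

    @property
    def depths(self) -> np.ndarray:
        return self.table["depth_mm"].to_numpy(float)

    def network_partition(self) -> dict:
        """Mapping parcel_id -> network label."""
        return dict(zip(self.table["parcel_id"], self.table["network"]))

    def parcels_in(self, networks) -> np.ndarray:
        """Boolean mask of parcels whose network is in *networks*."""
        networks = set(networks)
        return self.table["network"].isin(networks).to_numpy()

    def is_cortical(self) -> np.ndarray:
        return ~self.table["subcortical"].to_numpy(bool)

    # -- IO ---------------------------------------------------------------
    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ParcelAtlas":
        return cls(pd.read_csv(path, sep="\t", float_precision="round_trip"))

    def __repr__(self) -> str:  # pragma: no cover
        nets = self.table["network"].value_counts().to_dict()
        return f"ParcelAtlas(n_parcels={self.n_parcels}, networks={nets})"


def _depths_straddling_cutoff(n, rng, cutoff=30.0, deep_fraction=0.2):
    """Depths (mm) guaranteed to fall on both sides of *cutoff*.

    Roughly ``deep_fraction`` of parcels sit beyond the cutoff (sulcal
    depths / medial wall), the rest within TMS reach.
    """
    n_deep = max(1, int(round(deep_fraction * n)))
    n_shallow = max(1, n - n_deep)
    n_deep = n - n_shallow
    if n_deep < 1:  # n == 1 can't straddle; keep it reachable
        return rng.uniform(5.0, 25.0, size=n)
    shallow = rng.uniform(5.0, 28.0, size=n_shallow)
    deep = rng.uniform(32.0, 55.0, size=n_deep)
    depths = np.concatenate([shallow, deep])
    rng.shuffle(depths)
    return depths


def synthetic_atlas(n_parcels: int = 60, seed: int = 0,
                    n_subcortical: int = 0,
                    networks=NETWORKS) -> ParcelAtlas:
    """Generate a synthetic parcel atlas with plausible geometry.

    Cortical parcels are split evenly over *networks*, alternating
    hemispheres, with centroids on a spherical shell of radius ~70 mm and
    depths straddling the 30-mm TMS reach cutoff. Subcortical parcels (if
    any) are deep midline structures, network label "Subcortical".

    The names and coordinates are synthetic stand-ins for a multimodal
    cortical parcellation; they carry no anatomical meaning.
    """
    rng = np.random.default_rng(seed)
    n_cortical = n_parcels - n_subcortical
    if n_cortical < len(networks):
        raise ValueError("need at least one cortical parcel per network")
    rows = []
    per_net = np.full(len(networks), n_cortical // len(networks))
    per_net[: n_cortical % len(networks)] += 1
    depths = _depths_straddling_cutoff(n_cortical, rng)
    k = 0
    for net, cnt in zip(networks, per_net):
        for i in range(cnt):
            hemi = "L" if k % 2 == 0 else "R"
            # centroid on a shell whose radius encodes the depth
            theta = rng.uniform(0, np.pi)
            phi = rng.uniform(0, np.pi)  # one hemisphere of azimuth
            r = 80.0 - depths[k]
            x = r * np.sin(theta) * np.cos(phi) * (1 if hemi == "R" else -1)
            y = r * np.sin(theta) * np.sin(phi)
            z = r * np.cos(theta)
            rows.append(dict(
                parcel_id=k,
                name=f"{hemi}{net[:3].upper()}{i:03d}",
                hemisphere=hemi,
                location=f"{net} cortex {i}",
                network=net,
                depth_mm=float(depths[k]),
                x=float(x), y=float(y), z=float(z),
                subcortical=False,
            ))
            k += 1
    for i in range(n_subcortical):
        rows.append(dict(
            parcel_id=k,
            name=f"SC{i:02d}",
            hemisphere="L" if i % 2 == 0 else "R",
            location=f"Subcortical structure {i}",
            network="Subcortical",
            depth_mm=float(rng.uniform(50.0, 75.0)),
            x=float(rng.uniform(-15, 15)),
            y=float(rng.uniform(-30, 10)),
            z=float(rng.uniform(-20, 10)),
            subcortical=True,
        ))
        k += 1
    return ParcelAtlas(pd.DataFrame(rows))


def full_parity_atlas(seed: int = 0) -> ParcelAtlas:
    """Synthetic atlas at full study scale: 180 parcels x 2 hemispheres
    cortical plus 17 subcortical structures = 377 areas."""
    return synthetic_atlas(n_parcels=377, seed=seed, n_subcortical=17)
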