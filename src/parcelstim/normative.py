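"""Normative edge-wise model over a reference cohort, and anomaly scoring.

The model is fitted to a stack of reference tangent matrices: each
upper-triangle edge gets a cross-subject mean and sample SD. To curb false
discoveries, the highest-variance third of edges is excluded outright —
those connections are too noisy in healthy subjects to define a normal
range. A patient edge is anomalous when its z-score against the normative
distribution exceeds 3 in magnitude: hyperconnected above, hypoconnected
below.

API follows the model/results idiom: ``NormativeConnectivity(tangents)``
is the model, ``.fit()`` returns :class:`NormativeConnectivityResults`,
and ``results.score(subject_tangent)`` yields an :class:`AnomalyMatrix`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .atlas import ParcelAtlas

FLAG_NORMAL = "normal"
FLAG_HYPER = "hyper"
FLAG_HYPO = "hypo"
FLAG_EXCLUDED = "excluded"


class NormativeError(ValueError):
    pass


def edge_index(n_parcels: int):
    """Upper-triangle (i < j, 0-based) edge indexing shared package-wide."""
    return np.triu_indices(n_parcels, k=1)


def n_edges(n_parcels: int) -> int:
    return n_parcels * (n_parcels - 1) // 2


class NormativeConnectivity:
    """Edge-wise normative model of tangent connectivity.

    Parameters
    ----------
    tangents : sequence of (P, P) arrays or (S, P, P) array
        Reference-cohort tangent matrices, one per healthy subject.
    parcel_ids : list, optional
    min_subjects : int
        Floor on cohort size (default 10).
    """

    def __init__(self, tangents, parcel_ids=None, min_subjects: int = 10):
        stack = np.asarray(tangents, float)
        if stack.ndim != 3 or stack.shape[1] != stack.shape[2]:
            raise NormativeError("tangents must stack to (subjects, P, P)")
        if stack.shape[0] < min_subjects:
            raise NormativeError(
                f"need at least {min_subjects} reference subjects, "
                f"got {stack.shape[0]}")
        self.tangents = stack
        self.n_parcels = stack.shape[1]
        self.parcel_ids = (list(parcel_ids) if parcel_ids is not None
                           else list(range(self.n_parcels)))

    def fit(self, exclude_fraction: float = 1.0 / 3.0,
            sigma: float = 3.0) -> "NormativeConnectivityResults":
        """Estimate per-edge mean/SD and the variance-exclusion mask.

        Edges are ranked by cross-subject variance (descending); the top
        ``ceil(E * exclude_fraction)`` are excluded, ties at the cutoff
        broken by edge index ascending.
        """
        iu, ju = edge_index(self.n_parcels)
        edges = self.tangents[:, iu, ju]  # subjects x E
        mean = edges.mean(axis=0)
        sd = edges.std(axis=0, ddof=1)
        e = mean.size
        n_excl = math.ceil(e * exclude_fraction)
        order = np.lexsort((np.arange(e), -sd))  # variance desc, index asc
        excluded = np.zeros(e, dtype=bool)
        excluded[order[:n_excl]] = True
        if (sd[~excluded] == 0).any():
            bad = np.flatnonzero(~excluded & (sd == 0))[:5]
            raise NormativeError(
                f"zero SD on non-excluded edge(s) {bad.tolist()}: "
                "degenerate reference cohort")
        return NormativeConnectivityResults(
            edge_i=iu, edge_j=ju, mean=mean, sd=sd, excluded=excluded,
            n_reference=self.tangents.shape[0], n_parcels=self.n_parcels,
            parcel_ids=self.parcel_ids, sigma=sigma,
            exclude_fraction=exclude_fraction)


@dataclass
class NormativeConnectivityResults:
    """Fitted per-edge normative statistics plus the exclusion mask."""

    edge_i: np.ndarray
    edge_j: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    excluded: np.ndarray
    n_reference: int
    n_parcels: int
    parcel_ids: list
    sigma: float = 3.0
    exclude_fraction: float = 1.0 / 3.0

    @property
    def n_edges(self) -> int:
        return self.mean.size

    @property
    def n_excluded(self) -> int:
        return int(self.excluded.sum())

    def score(self, tangent: np.ndarray, sigma: float = None,
              subject_id=None) -> "AnomalyMatrix":
        """Score one subject's tangent matrix against the normative model.

        z = (t_e - mean_e) / sd_e on non-excluded edges; flags at strict
        |z| > sigma.
        """
        sigma = self.sigma if sigma is None else sigma
        tangent = np.asarray(tangent, float)
        if tangent.shape != (self.n_parcels, self.n_parcels):
            raise NormativeError(
                f"subject matrix shape {tangent.shape} does not match "
                f"model ({self.n_parcels} parcels)")
        vals = tangent[self.edge_i, self.edge_j]
        z = np.full(self.n_edges, np.nan)
        ok = ~self.excluded
        z[ok] = (vals[ok] - self.mean[ok]) / self.sd[ok]
        flags = np.full(self.n_edges, FLAG_NORMAL, dtype=object)
        flags[self.excluded] = FLAG_EXCLUDED
        flags[ok & (z > sigma)] = FLAG_HYPER
        flags[ok & (z < -sigma)] = FLAG_HYPO
        return AnomalyMatrix(
            edge_i=self.edge_i.copy(), edge_j=self.edge_j.copy(),
            z=z, flags=flags, n_parcels=self.n_parcels,
            parcel_ids=list(self.parcel_ids), sigma=sigma,
            subject_id=subject_id)

    def summary(self) -> str:
        lines = [
            "Normative tangent-connectivity model",
            "=" * 40,
            f"Reference subjects        {self.n_reference}",
            f"Parcels                   {self.n_parcels}",
            f"Edges (unordered pairs)   {self.n_edges}",
            f"Excluded (high variance)  {self.n_excluded} "
            f"({self.n_excluded / self.n_edges:.1%})",
            f"Anomaly threshold         |z| > {self.sigma:g}",
            f"Median edge SD (retained) "
            f"{np.median(self.sd[~self.excluded]):.4f}",
        ]
        return "\n".join(lines)

    # -- IO ---------------------------------------------------------------
    def to_tsv(self, path) -> None:
        pd.DataFrame({
            "edge_i": self.edge_i, "edge_j": self.edge_j,
            "mean": self.mean, "sd": self.sd,
            "excluded": self.excluded.astype(int),
        }).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, n_reference: int, sigma: float = 3.0):
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
        e = len(df)
        p = int(round((1 + math.sqrt(1 + 8 * e)) / 2))
        return cls(edge_i=df["edge_i"].to_numpy(),
                   edge_j=df["edge_j"].to_numpy(),
                   mean=df["mean"].to_numpy(float),
                   sd=df["sd"].to_numpy(float),
                   excluded=df["excluded"].to_numpy(bool),
                   n_reference=n_reference, n_parcels=p,
                   parcel_ids=list(range(p)), sigma=sigma)


def fit_normative(tangents, parcel_ids=None,
                  exclude_fraction: float = 1.0 / 3.0,
                  min_subjects: int = 10) -> NormativeConnectivityResults:
    """Functional alias for ``NormativeConnectivity(...).fit(...)``."""
    return NormativeConnectivity(
        tangents, parcel_ids, min_subjects).fit(exclude_fraction)


def score_subject(tangent, results: NormativeConnectivityResults,
                  sigma: float = None) -> "AnomalyMatrix":
    """Functional alias for ``results.score(tangent)``."""
    return results.score(tangent, sigma=sigma)


@dataclass
class AnomalyMatrix:
    """Edge-wise anomaly calls for one subject.

    ``z`` is NaN on variance-excluded edges; flags are one of hyper, hypo,
    normal, excluded. ``networks_in_scope`` records any network restriction
    applied (None = all networks); restriction re-flags out-of-scope edges
    as excluded but keeps their z for audit.
    """

    edge_i: np.ndarray
    edge_j: np.ndarray
    z: np.ndarray
    flags: np.ndarray
    n_parcels: int
    parcel_ids: list
    sigma: float = 3.0
    subject_id: object = None
    networks_in_scope: frozenset = None
    meta: dict = field(default_factory=dict)

    @property
    def n_edges(self) -> int:
        return self.z.size

    def counts(self) -> dict:
        f = pd.Series(self.flags)
        out = {k: int((f == k).sum())
               for k in (FLAG_HYPER, FLAG_HYPO, FLAG_NORMAL, FLAG_EXCLUDED)}
        return out

    def anomalous_edges(self) -> pd.DataFrame:
        keep = np.isin(self.flags, [FLAG_HYPER, FLAG_HYPO])
        return pd.DataFrame({
            "edge_i": self.edge_i[keep], "edge_j": self.edge_j[keep],
            "z": self.z[keep], "flag": self.flags[keep]})

    def restrict_networks(self, atlas: ParcelAtlas,
                          networks) -> "AnomalyMatrix":
        """Keep only edges with BOTH endpoints in the named networks.

        Out-of-scope edges are re-flagged excluded (z retained). Cross-
        network edges among several implicated networks survive when all
        those networks are passed together.
        """
        networks = frozenset(networks)
        if not networks:
            raise NormativeError("empty network set")
        known = set(atlas.networks.unique())
        unknown = networks - known
        if unknown:
            raise NormativeError(f"networks not in atlas: {sorted(unknown)}")
        in_scope_parcel = atlas.parcels_in(networks)
        if len(in_scope_parcel) != self.n_parcels:
            raise NormativeError("atlas size does not match anomaly matrix")
        edge_ok = in_scope_parcel[self.edge_i] & in_scope_parcel[self.edge_j]
        flags = self.flags.copy()
        flags[~edge_ok] = FLAG_EXCLUDED
        return replace(self, flags=flags, networks_in_scope=networks,
                       z=self.z.copy(), edge_i=self.edge_i.copy(),
                       edge_j=self.edge_j.copy(),
                       parcel_ids=list(self.parcel_ids))

    def flag_matrix(self) -> np.ndarray:
        """Square (P, P) array of flag codes: 0 normal (and diagonal),
        1 hyper, 2 hypo, 3 excluded."""
        code = {FLAG_NORMAL: 0, FLAG_HYPER: 1, FLAG_HYPO: 2,
                FLAG_EXCLUDED: 3}
        m = np.zeros((self.n_parcels, self.n_parcels), dtype=int)
        vals = np.array([code[f] for f in self.flags])
        m[self.edge_i, self.edge_j] = vals
        m[self.edge_j, self.edge_i] = vals
        return m

    def z_matrix(self) -> np.ndarray:
        m = np.full((self.n_parcels, self.n_parcels), np.nan)
        m[self.edge_i, self.edge_j] = self.z
        m[self.edge_j, self.edge_i] = self.z
        np.fill_diagonal(m, 0.0)
        return m

    # -- IO ---------------------------------------------------------------
    def to_tsv(self, path) -> None:
        pd.DataFrame({
            "edge_i": self.edge_i, "edge_j": self.edge_j,
            "z": self.z, "flag": self.flags,
        }).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, sigma: float = 3.0):
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
        e = len(df)
        p = int(round((1 + math.sqrt(1 + 8 * e)) / 2))
        return cls(edge_i=df["edge_i"].to_numpy(),
                   edge_j=df["edge_j"].to_numpy(),
                   z=df["z"].to_numpy(float),
                   flags=df["flag"].to_numpy(object),
                   n_parcels=p, parcel_ids=list(range(p)), sigma=sigma)


def restrict_networks(a: AnomalyMatrix, atlas: ParcelAtlas,
                      networks) -> AnomalyMatrix:
    """Functional alias for ``a.restrict_networks(atlas, networks)``."""
    return a.restrict_networks(atlas, networks)


def render_anomaly_heatmap(a: AnomalyMatrix, path, title=None) -> None:
    """Write the anomaly matrix as a PNG heatmap.

    Color convention: hyperconnected edges red, hypoconnected blue, edges
    within the normal range white, and variance-excluded (too noisy to
    define a normal range) black.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    cmap = ListedColormap(["white", "red", "blue", "black"])
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(a.flag_matrix(), cmap=cmap, vmin=0, vmax=3,
              interpolation="nearest")
    ax.set_xlabel("parcel")
    ax.set_ylabel("parcel")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
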