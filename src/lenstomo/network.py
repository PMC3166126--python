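"""Class-paired Euclidean connection networks.

A *connection* links two classified particles whose mass centers lie
strictly closer than the cutoff for their class pair: 10 nm for
blue-blue, 28 nm for blue-yellow and 32 nm for yellow-yellow in labeled
maps (the unlabeled preset uses 24 nm for blue-yellow).  All pairs below
the cutoff are connected, not just the single nearest neighbor; a
k-nearest restriction is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from sklearn.base import BaseEstimator

PAIR_TYPES = ("blue_blue", "blue_yellow", "yellow_yellow")


@dataclass
class CutoffPolicy:
    """Per-pair-type upper distance limits in nm (strict inequality)."""

    blue_blue: float = 10.0
    blue_yellow: float = 28.0
    yellow_yellow: float = 32.0

    def __post_init__(self) -> None:
        if min(self.blue_blue, self.blue_yellow, self.yellow_yellow) <= 0:
            raise ValueError("cutoffs must be > 0")

    @classmethod
    def labeled(cls) -> "CutoffPolicy":
        return cls(10.0, 28.0, 32.0)

    @classmethod
    def unlabeled(cls) -> "CutoffPolicy":
        return cls(10.0, 24.0, 32.0)

    def cutoff(self, pair_type: str) -> float:
        return getattr(self, pair_type)

    @property
    def max_cutoff(self) -> float:
        return max(self.blue_blue, self.blue_yellow, self.yellow_yellow)


def _pair_type(class_a: str, class_b: str) -> str:
    return "_".join(sorted((class_a, class_b), key=("blue", "yellow").index))


class ConnectionNetwork(BaseEstimator):
    """Builds the connection table for a classified particle table.

    Only blue/yellow particles take part (aggregates and unclassified
    particles are ignored).  Every unordered pair with Euclidean center
    distance strictly below its pair-type cutoff becomes one connection;
    the output is in canonical form (``a < b``) sorted by
    (pair_type, distance).  ``k_nearest`` optionally restricts pairs to
    those where at least one endpoint ranks among the other's k nearest
    participating particles.
    """

    def __init__(self, policy: CutoffPolicy | None = None,
                 k_nearest: int | None = None):
        self.policy = policy
        self.k_nearest = k_nearest

    def fit(self, particles: pd.DataFrame, y=None) -> "ConnectionNetwork":
        self.connections_ = self.transform(particles)
        return self

    def transform(self, particles: pd.DataFrame) -> pd.DataFrame:
        policy = self.policy if self.policy is not None else CutoffPolicy.labeled()
        sel = particles[particles["class"].isin(["blue", "yellow"])]
        ids = sel["id"].to_numpy()
        classes = sel["class"].to_numpy()
        xyz = sel[["x_nm", "y_nm", "z_nm"]].to_numpy(dtype=float)
        if len(sel) < 2:
            return _empty_connections()

        tree = cKDTree(xyz)
        pairs = np.array(sorted(tree.query_pairs(policy.max_cutoff)))
        if len(pairs) == 0:
            return _empty_connections()

        if self.k_nearest is not None:
            k = min(self.k_nearest + 1, len(sel))
            _, nbrs = tree.query(xyz, k=k)
            nbr_sets = [set(row[1:]) for row in np.atleast_2d(nbrs)]
            keep = np.array([(j in nbr_sets[i]) or (i in nbr_sets[j])
                             for i, j in pairs])
            pairs = pairs[keep]
            if len(pairs) == 0:
                return _empty_connections()

        dists = np.linalg.norm(xyz[pairs[:, 0]] - xyz[pairs[:, 1]], axis=1)
        ptypes = np.array([_pair_type(classes[i], classes[j]) for i, j in pairs])
        cutoffs = np.array([policy.cutoff(t) for t in ptypes])
        keep = dists < cutoffs
        a = np.minimum(ids[pairs[keep, 0]], ids[pairs[keep, 1]])
        b = np.maximum(ids[pairs[keep, 0]], ids[pairs[keep, 1]])
        df = pd.DataFrame({"a": a, "b": b, "pair_type": ptypes[keep],
                           "distance_nm": dists[keep]})
        df["pair_type"] = pd.Categorical(df["pair_type"], categories=PAIR_TYPES)
        df = df.sort_values(["pair_type", "distance_nm", "a", "b"],
                            kind="stable").reset_index(drop=True)
        df["pair_type"] = df["pair_type"].astype(str)
        return df

    fit_transform = transform


def _empty_connections() -> pd.DataFrame:
    return pd.DataFrame({"a": pd.Series(dtype=int), "b": pd.Series(dtype=int),
                         "pair_type": pd.Series(dtype=object),
                         "distance_nm": pd.Series(dtype=float)})


def build_connections(particles: pd.DataFrame,
                      policy: CutoffPolicy | None = None,
                      k_nearest: int | None = None) -> pd.DataFrame:
    """Build the class-paired connection table (see
    :class:`ConnectionNetwork`)."""
    return ConnectionNetwork(policy=policy, k_nearest=k_nearest).transform(particles)


def connection_counts(connections: pd.DataFrame) -> dict:
    out = {t: 0 for t in PAIR_TYPES}
    if len(connections):
        out.update(connections["pair_type"].value_counts().to_dict())
    return out


def distance_histogram(connections: pd.DataFrame, pair_type: str,
                       bin_width: float = 1.0,
                       upper: float | None = None) -> dict:
    """Histogram of connection distances for one pair type.

    Bins cover [0, upper) with fixed ``bin_width`` (``upper`` defaults to
    the largest distance rounded up to a bin edge).  The raw distances
    are returned alongside the binned counts for unbinned fitting.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    if pair_type not in PAIR_TYPES:
        raise ValueError(f"pair_type must be one of {PAIR_TYPES}")
    distances = connections.loc[connections["pair_type"] == pair_type,
                                "distance_nm"].to_numpy(dtype=float)
    if upper is None:
        upper = bin_width * (np.ceil(distances.max() / bin_width) + 1) \
            if len(distances) else bin_width
    edges = np.arange(0.0, upper + bin_width / 2, bin_width)
    counts, edges = np.histogram(distances, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2.0
    return {"pair_type": pair_type, "bin_centers": centers, "counts": counts,
            "distances": distances}
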