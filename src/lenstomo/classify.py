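"""Particle classification and aggregate exclusion.

Labeled mode reproduces the gold-conjugate classification used for
immunogold maps: a particle is *yellow* when its equivalent diameter
exceeds 4 nm OR its peak intensity exceeds 200, otherwise *blue* when
diameter exceeds 2 nm OR intensity exceeds 150, otherwise unclassified.
The yellow rule is evaluated first; this sequential precedence is what
makes the classes disjoint (the blue rule alone would also accept every
yellow particle).

Unlabeled mode classifies protein densities purely by diameter band:
blue in (2, 3.5) nm, yellow in (3.5, 7) nm by default (a (3.5, 5) nm
preset is also provided), and *aggregate* above 7 nm.  Aggregates can be
excluded either geometrically (corner octant of the analyzed box) or by
their abundance of connections in the distance network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

BLUE, YELLOW, AGGREGATE, UNCLASSIFIED = "blue", "yellow", "aggregate", "unclassified"


@dataclass
class ClassificationRules:
    mode: str = "labeled"                      # labeled | unlabeled
    labeled_yellow_diameter_gt: float = 4.0
    labeled_yellow_intensity_gt: float = 200.0
    labeled_blue_diameter_gt: float = 2.0
    labeled_blue_intensity_gt: float = 150.0
    unlabeled_blue_band: tuple = (2.0, 3.5)    # exclusive bounds, nm
    unlabeled_yellow_band: tuple = (3.5, 7.0)
    aggregate_diameter_gt: float = 7.0

    def __post_init__(self) -> None:
        if self.mode not in ("labeled", "unlabeled"):
            raise ValueError("mode must be 'labeled' or 'unlabeled'")
        b, y = self.unlabeled_blue_band, self.unlabeled_yellow_band
        if not (b[0] < b[1] <= y[0] < y[1]):
            raise ValueError("diameter bands must be ordered and non-overlapping")

    @classmethod
    def labeled(cls) -> "ClassificationRules":
        return cls(mode="labeled")

    @classmethod
    def labeled_diameter_only(cls) -> "ClassificationRules":
        """Labeled rules with the intensity branches disabled.

        Appropriate when gold saturates the 8-bit range uniformly (as in
        rasterized synthetic scenes), leaving diameter as the only
        discriminating measurement.  Thresholds of 255 can never be
        exceeded by 8-bit data.
        """
        return cls(mode="labeled", labeled_yellow_intensity_gt=255.0,
                   labeled_blue_intensity_gt=255.0)

    @classmethod
    def unlabeled(cls) -> "ClassificationRules":
        """Unlabeled preset with the (3.5, 7) nm yellow band."""
        return cls(mode="unlabeled")

    @classmethod
    def unlabeled_narrow_yellow(cls) -> "ClassificationRules":
        """Unlabeled preset with the alternative (3.5, 5) nm yellow band."""
        return cls(mode="unlabeled", unlabeled_yellow_band=(3.5, 5.0))


class GoldClassifier(BaseEstimator):
    """Rule-based particle classifier (labeled or unlabeled mode).

    ``predict`` maps a particle table to an array of class labels;
    ``transform`` returns a copy of the table with the ``class`` column
    filled in.  Classification depends only on the ``diameter_nm`` and
    (labeled mode) ``peak_intensity`` columns and is idempotent.
    """

    def __init__(self, rules: ClassificationRules | None = None):
        self.rules = rules

    def _rules(self) -> ClassificationRules:
        return self.rules if self.rules is not None else ClassificationRules.labeled()

    def fit(self, particles: pd.DataFrame, y=None) -> "GoldClassifier":
        return self

    def predict(self, particles: pd.DataFrame) -> np.ndarray:
        r = self._rules()
        d = particles["diameter_nm"].to_numpy(dtype=float)
        labels = np.full(len(particles), UNCLASSIFIED, dtype=object)
        if r.mode == "labeled":
            i = particles["peak_intensity"].to_numpy(dtype=float)
            yellow = (d > r.labeled_yellow_diameter_gt) | (i > r.labeled_yellow_intensity_gt)
            blue = (d > r.labeled_blue_diameter_gt) | (i > r.labeled_blue_intensity_gt)
            labels[blue] = BLUE
            labels[yellow] = YELLOW          # yellow precedence over blue
        else:
            b, y = r.unlabeled_blue_band, r.unlabeled_yellow_band
            labels[(d > b[0]) & (d < b[1])] = BLUE
            labels[(d > y[0]) & (d < y[1])] = YELLOW
            labels[d > r.aggregate_diameter_gt] = AGGREGATE
        return labels

    def transform(self, particles: pd.DataFrame) -> pd.DataFrame:
        out = particles.copy()
        out["class"] = self.predict(particles)
        return out

    fit_transform = transform


def classify_labeled(particles: pd.DataFrame,
                     rules: ClassificationRules | None = None) -> pd.DataFrame:
    """Assign yellow/blue/unclassified labels with the labeled-mode rules."""
    r = rules or ClassificationRules.labeled()
    if r.mode != "labeled":
        raise ValueError("classify_labeled requires labeled-mode rules")
    return GoldClassifier(r).transform(particles)


def classify_unlabeled(particles: pd.DataFrame,
                       rules: ClassificationRules | None = None) -> pd.DataFrame:
    """Assign blue/yellow/aggregate labels by diameter band."""
    r = rules or ClassificationRules.unlabeled()
    if r.mode != "unlabeled":
        raise ValueError("classify_unlabeled requires unlabeled-mode rules")
    return GoldClassifier(r).transform(particles)


def class_counts(particles: pd.DataFrame) -> dict:
    return particles["class"].value_counts().to_dict()


def exclude_aggregates_geometric(particles: pd.DataFrame, box_lower, box_upper,
                                 corner=(1, 1, 1)) -> pd.DataFrame:
    """Drop aggregate particles whose centers fall in one corner octant.

    ``corner`` selects, per axis, which half of the box belongs to the
    excluded octant (1 = upper / maximum-coordinate half, 0 = lower).
    Non-aggregate particles are always retained.
    """
    lo = np.asarray(box_lower, float)
    hi = np.asarray(box_upper, float)
    mid = (lo + hi) / 2.0
    xyz = particles[["x_nm", "y_nm", "z_nm"]].to_numpy(dtype=float)
    in_octant = np.ones(len(particles), dtype=bool)
    for ax in range(3):
        if corner[ax]:
            in_octant &= xyz[:, ax] >= mid[ax]
        else:
            in_octant &= xyz[:, ax] < mid[ax]
    drop = in_octant & (particles["class"].to_numpy() == AGGREGATE)
    return particles.loc[~drop].reset_index(drop=True)


def connection_degrees(particles: pd.DataFrame,
                       connections: pd.DataFrame) -> pd.Series:
    """Connection-graph degree per particle id (0 for isolated particles)."""
    deg = pd.Series(0, index=particles["id"].to_numpy(), dtype=int)
    if len(connections):
        counts = pd.concat([connections["a"], connections["b"]]).value_counts()
        deg.loc[counts.index.intersection(deg.index)] = \
            counts[counts.index.intersection(deg.index)]
    return deg


def exclude_aggregates_by_connectivity(particles: pd.DataFrame,
                                       connections: pd.DataFrame,
                                       max_degree: int | None = None,
                                       percentile: float = 98.0) -> pd.DataFrame:
    """Drop particles with an unusually large number of connections.

    Densely interconnected groups are characteristic of aggregates; a
    particle is removed when its degree in the connection graph exceeds
    ``max_degree`` (default: the ``percentile``-th percentile of the
    degree distribution).
    """
    if len(connections) == 0:
        return particles.reset_index(drop=True)
    deg = connection_degrees(particles, connections)
    cut = float(max_degree) if max_degree is not None \
        else float(np.percentile(deg.to_numpy(), percentile))
    keep = particles["id"].map(deg) <= cut
    return particles.loc[keep.to_numpy()].reset_index(drop=True)
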