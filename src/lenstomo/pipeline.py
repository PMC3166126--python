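"""End-to-end labeled-cell and unlabeled-cell analyses.

The labeled pipeline mirrors the immunogold workflow: split the
tomogram into gold map + reference space, segment the gold map,
classify conjugates yellow/blue, build the class-paired connection
network, fit Gaussian spacing models, and detect geometric motifs.

The unlabeled pipeline segments the protein densities directly,
classifies them by diameter band, excludes aggregates (geometric corner
constraint and/or connectivity), rebuilds the network, fits spacing
models and estimates molecular masses from mean class volumes.

Every stage is deterministic under the configured seed; the report
carries the configuration hash and package version for provenance, and
stage outputs can be written as flat TSV/JSON files so any stage can be
rerun in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from lenstomo.classify import (ClassificationRules, classify_labeled,
                               classify_unlabeled, exclude_aggregates_geometric,
                               exclude_aggregates_by_connectivity)
from lenstomo.motifs import (detect_files, detect_polyhedra, estimate_mass,
                             motif_counts, motifs_to_frame)
from lenstomo.network import (CutoffPolicy, PAIR_TYPES, build_connections,
                              connection_counts)
from lenstomo.segmentation import (SegmentationParams, segment_particles,
                                   split_gold_reference,
                                   GOLD_THRESHOLD_DEFAULT,
                                   PROTEIN_THRESHOLD_DEFAULT)
from lenstomo.spacing import (fit_spacing_model, select_n_components,
                              spacing_multiple_report)
from lenstomo.volume import (DensityVolume, write_connection_table,
                             write_particle_table)


@dataclass
class PipelineConfig:
    """Parameters for a full labeled- or unlabeled-mode run."""

    mode: str = "labeled"
    seed: int = 1
    gold_threshold: float = GOLD_THRESHOLD_DEFAULT
    segmentation: SegmentationParams = field(
        default_factory=lambda: SegmentationParams(
            intensity_threshold=GOLD_THRESHOLD_DEFAULT))
    rules: ClassificationRules = field(default_factory=ClassificationRules.labeled)
    cutoffs: CutoffPolicy = field(default_factory=CutoffPolicy.labeled)
    #: components per pair type: 1, 2, or "auto" (BIC selection)
    components: dict = field(default_factory=lambda: {
        "blue_blue": 1, "blue_yellow": 2, "yellow_yellow": 2})
    #: histogram_least_squares | mixture_likelihood | windowed_peak
    fit_method: str = "mixture_likelihood"
    truncate_at_cutoff: bool = True
    #: random-pair background handling in likelihood fits:
    #: "csr" fixes the background weight at the complete-spatial-randomness
    #: expectation for the observed particle density, "free" fits it,
    #: "none" omits it
    fit_background: str = "csr"
    bin_width: float = 1.0
    min_connections_for_fit: int = 10
    #: unlabeled mode: aggregate exclusion strategy
    exclusion: str = "connectivity"   # geometric | connectivity | both | none
    aggregate_max_degree: int | None = None
    corner: tuple = (1, 1, 1)
    collinearity_tol: float = 1.5
    spacing_tol: float = 0.2
    edge_tol: float = 0.2
    detect_motifs: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("labeled", "unlabeled"):
            raise ValueError("mode must be 'labeled' or 'unlabeled'")
        if self.exclusion not in ("geometric", "connectivity", "both", "none"):
            raise ValueError("unknown exclusion strategy")
        if self.fit_background not in ("none", "free", "csr"):
            raise ValueError("fit_background must be 'none', 'free' or 'csr'")

    @classmethod
    def labeled(cls, **overrides) -> "PipelineConfig":
        return cls(mode="labeled", **overrides)

    @classmethod
    def unlabeled(cls, **overrides) -> "PipelineConfig":
        defaults = dict(
            mode="unlabeled",
            segmentation=SegmentationParams(
                intensity_threshold=PROTEIN_THRESHOLD_DEFAULT),
            rules=ClassificationRules.unlabeled(),
            cutoffs=CutoffPolicy.unlabeled(),
            components={"blue_blue": 1, "blue_yellow": 1, "yellow_yellow": 1},
        )
        defaults.update(overrides)
        return cls(**defaults)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["corner"] = list(self.corner)
        d["rules"] = asdict(self.rules)
        d["rules"]["unlabeled_blue_band"] = list(self.rules.unlabeled_blue_band)
        d["rules"]["unlabeled_yellow_band"] = list(self.rules.unlabeled_yellow_band)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _class_table(particles: pd.DataFrame) -> list:
    rows = []
    for cls in ("blue", "yellow", "aggregate", "unclassified"):
        sub = particles[particles["class"] == cls]
        if len(sub) == 0:
            continue
        rows.append({
            "class": cls,
            "number": int(len(sub)),
            "mean_diameter_nm": float(sub["diameter_nm"].mean()),
            "sd_diameter_nm": float(sub["diameter_nm"].std(ddof=1)) if len(sub) > 1 else 0.0,
            "mean_volume_nm3": float(sub["volume_nm3"].mean()),
            "sd_volume_nm3": float(sub["volume_nm3"].std(ddof=1)) if len(sub) > 1 else 0.0,
        })
    return rows


def _csr_background_weight(pair_type: str, n_connections: int, counts: dict,
                           cutoff: float, box_volume: float) -> float:
    """Fraction of connections expected from uniformly random particle
    placement (complete spatial randomness) at the observed density."""
    n_b, n_y = counts.get("blue", 0), counts.get("yellow", 0)
    pairs = {"blue_blue": n_b * (n_b - 1) / 2.0,
             "blue_yellow": float(n_b * n_y),
             "yellow_yellow": n_y * (n_y - 1) / 2.0}[pair_type]
    if box_volume <= 0 or n_connections == 0:
        return 0.0
    expected = pairs * (4.0 * np.pi / 3.0) * cutoff ** 3 / box_volume
    return float(min(expected / n_connections, 0.5))


def _fit_models(connections: pd.DataFrame, config: PipelineConfig,
                class_counts: dict, box_volume: float) -> dict:
    models = {}
    for pair_type in PAIR_TYPES:
        dists = connections.loc[connections["pair_type"] == pair_type,
                                "distance_nm"].to_numpy(dtype=float)
        if len(dists) < config.min_connections_for_fit:
            continue
        cutoff = config.cutoffs.cutoff(pair_type)
        likelihood = config.fit_method == "mixture_likelihood"
        truncation = (0.0, cutoff) if (config.truncate_at_cutoff and likelihood) \
            else None
        background = False
        fixed_bg = None
        if likelihood and truncation is not None:
            if config.fit_background == "free":
                background = True
            elif config.fit_background == "csr":
                fixed_bg = _csr_background_weight(pair_type, len(dists),
                                                  class_counts, cutoff,
                                                  box_volume)
        want = config.components.get(pair_type, 1)
        if config.fit_method == "windowed_peak":
            want = 1
        elif want == "auto":
            want = select_n_components(dists, seed=config.seed,
                                       truncation=truncation,
                                       background=background)
        models[pair_type] = fit_spacing_model(
            dists, n_components=want, method=config.fit_method,
            seed=config.seed, truncation=truncation, background=background,
            background_weight_fixed=fixed_bg,
            bin_width=config.bin_width, pair_type=pair_type)
    return models


def _distance_table(connections: pd.DataFrame, models: dict,
                    config: PipelineConfig) -> list:
    counts = connection_counts(connections)
    rows = []
    for pair_type in PAIR_TYPES:
        row = {"type": pair_type,
               "upper_limit_nm": config.cutoffs.cutoff(pair_type),
               "connection_number": int(counts.get(pair_type, 0)),
               "gaussian_centers": []}
        if pair_type in models:
            row["gaussian_centers"] = [
                {"center_nm": c.center, "hwhm_nm": c.hwhm, "weight": c.weight}
                for c in models[pair_type].components]
        rows.append(row)
    return rows


def run_pipeline(config: PipelineConfig,
                 vol: DensityVolume | None = None,
                 particles: pd.DataFrame | None = None,
                 outdir: str | os.PathLike | None = None) -> dict:
    """Run the full analysis and return the report dictionary.

    Either a density volume or a pre-measured particle table must be
    given; the table bypasses segmentation (useful for ideal
    ground-truth tables).
    """
    if vol is None and particles is None:
        raise ValueError("provide a volume or a particle table")

    stage = "segmentation"
    try:
        if particles is None:
            if config.mode == "labeled":
                gold_map, _ref = split_gold_reference(vol, config.gold_threshold)
                particles = segment_particles(gold_map, config.segmentation)
            else:
                particles = segment_particles(vol, config.segmentation)
        n_segmented = int(len(particles))

        stage = "classification"
        if config.mode == "labeled":
            classified = classify_labeled(particles, config.rules)
        else:
            classified = classify_unlabeled(particles, config.rules)

        stage = "aggregate_exclusion"
        excluded = 0
        if config.mode == "unlabeled" and config.exclusion != "none":
            before = len(classified)
            if config.exclusion in ("connectivity", "both"):
                pre = build_connections(classified, config.cutoffs)
                classified = exclude_aggregates_by_connectivity(
                    classified, pre, max_degree=config.aggregate_max_degree)
            if config.exclusion in ("geometric", "both"):
                if vol is not None:
                    lo = vol.origin
                    hi = vol.origin + vol.voxel_size * (np.array(vol.shape) - 1)
                else:
                    lo = classified[["x_nm", "y_nm", "z_nm"]].min().to_numpy()
                    hi = classified[["x_nm", "y_nm", "z_nm"]].max().to_numpy()
                classified = exclude_aggregates_geometric(classified, lo, hi,
                                                          corner=config.corner)
            excluded = before - len(classified)

        stage = "connections"
        connections = build_connections(classified, config.cutoffs)

        stage = "gaussian_fits"
        if vol is not None:
            box_volume = float(np.prod(np.array(vol.shape) * vol.voxel_size))
        else:
            extent = (classified[["x_nm", "y_nm", "z_nm"]].max()
                      - classified[["x_nm", "y_nm", "z_nm"]].min()).to_numpy()
            box_volume = float(np.prod(np.maximum(extent, 1.0)))
        counts = classified["class"].value_counts().to_dict()
        models = _fit_models(connections, config, counts, box_volume)
        ratios = spacing_multiple_report(models) if "blue_blue" in models else []

        stage = "motifs"
        motifs = []
        if config.detect_motifs:
            motifs = (detect_files(classified, connections,
                                   config.collinearity_tol, config.spacing_tol)
                      + detect_polyhedra(classified, connections, config.edge_tol))

        stage = "report"
        report = {
            "mode": config.mode,
            "seed": config.seed,
            "n_segmented": n_segmented,
            "n_excluded_aggregates": excluded,
            "class_table": _class_table(classified),
            "distance_table": _distance_table(connections, models, config),
            "spacing_multiples": ratios,
            "motif_counts": motif_counts(motifs),
            "provenance": {
                "package": "lenstomo",
                "version": _package_version(),
                "config": config.to_dict(),
                "config_sha256": config.config_hash(),
            },
        }
        if config.mode == "unlabeled":
            report["mass_estimates"] = {}
            for row in report["class_table"]:
                if row["class"] in ("blue", "yellow") and row["mean_volume_nm3"] > 0:
                    est = estimate_mass(row["mean_volume_nm3"])
                    report["mass_estimates"][row["class"]] = {
                        "mean_volume_nm3": est.volume_nm3,
                        "mass_da": est.mass_da,
                        "mass_kda_rounded": est.mass_kda_rounded,
                    }
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        write_particle_table(classified, os.path.join(outdir, "particles.tsv"))
        write_connection_table(connections, os.path.join(outdir, "connections.tsv"))
        if motifs:
            motifs_to_frame(motifs).to_csv(
                os.path.join(outdir, "motifs.tsv"), sep="\t", index=False)
        with open(os.path.join(outdir, "report.json"), "w") as fh:
            fh.write(report_to_json(report))
    return report


def report_to_json(report: dict) -> str:
    """Canonical (byte-stable) JSON rendering of a pipeline report."""
    return json.dumps(report, sort_keys=True, indent=2,
                      default=_json_default) + "\n"


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _package_version() -> str:
    from lenstomo import __version__
    return __version__
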