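"""End-to-end orchestration: configuration, the full run, provenance.

The run configuration bundles every tolerance and threshold of the
three network builders and the propagation stage.  Defaults are the
standard published operating point for qToF data: 10 ppm mass-difference
matching, 0.02 u fragment tolerance, minimum cosine 0.8 with at least 3
matched fragment ions and (effectively unrestrictive) top-1000
neighbours, series units of 5-60 Da with RT shifts of 12-60 s (5 s
tolerance) and at least 4 members.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from .formula import TransformationList, bundled_transformations
from .homologs import SeriesParams, find_homologous_series
from .io import (
    Feature,
    SeedAnnotation,
    Spectrum,
    match_spectra_to_features,
    write_annotation_table,
    write_level_summary,
)
from .massdiff import build_massdiff_network
from .merge import MergedNetwork, merge_networks, write_graphml
from .propagate import (
    PropagatedAnnotation,
    cross_validate,
    propagate,
    resolve,
    summarize_levels,
)
from .spectral import build_spectral_network

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "build_merged_network"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Flat run configuration; round-trips through YAML."""

    ppm: float = 10.0
    frag_tol: float = 0.02
    min_cosine: float = 0.8
    min_matched: int = 3
    top_k: int = 1000
    intensity_power: float = 0.5
    cosine_method: str = "greedy"
    series_min_unit: float = 5.0
    series_max_unit: float = 60.0
    series_range_tol: float = 5.0
    series_unit_tol: float = 0.005
    series_min_rt_shift: float = 12.0
    series_max_rt_shift: float = 60.0
    series_rt_tol: float = 5.0
    series_min_members: int = 4
    second_neighbor_min_types: int = 3
    polarity: str = "negative"
    rt_unit: str = "s"
    transformation_list: str = "gpnae"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("ppm", "frag_tol", "min_cosine", "series_unit_tol",
                     "series_rt_tol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"config field {name!r} must be positive")

    def series_params(self) -> SeriesParams:
        return SeriesParams(
            min_unit=self.series_min_unit,
            max_unit=self.series_max_unit,
            range_tol=self.series_range_tol,
            unit_tol=self.series_unit_tol,
            min_rt_shift=self.series_min_rt_shift,
            max_rt_shift=self.series_max_rt_shift,
            rt_tol=self.series_rt_tol,
            min_members=self.series_min_members,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


@dataclass
class PipelineResult:
    network: MergedNetwork
    raw_annotations: list[PropagatedAnnotation]
    resolved: list[PropagatedAnnotation]
    summary: dict[str, int]
    n_spectral_edges: int
    n_massdiff_edges: int
    n_series: int


def build_merged_network(
    features: Sequence[Feature],
    spectra: Sequence[Spectrum],
    transformations: TransformationList | None,
    config: RunConfig = RunConfig(),
) -> tuple[MergedNetwork, int, int, int]:
    """Run the three builders and merge; returns the network plus the
    spectral-edge, mass-difference-candidate and series counts."""
    if transformations is None:
        transformations = bundled_transformations(config.transformation_list)
    spectra = match_spectra_to_features(spectra, features)
    spectral = build_spectral_network(
        spectra,
        frag_tol=config.frag_tol,
        min_cosine=config.min_cosine,
        min_matched=config.min_matched,
        top_k=config.top_k,
        intensity_power=config.intensity_power,
        method=config.cosine_method,
    )
    massdiff = build_massdiff_network(features, transformations, ppm=config.ppm)
    series = find_homologous_series(features, config.series_params())
    net = merge_networks(spectral, massdiff, series, features)
    log.info(
        "networks: %d spectral edges, %d massdiff candidates, %d series; "
        "merged: %d nodes, %d edges",
        len(spectral), len(massdiff), len(series), net.n_nodes, net.n_edges,
    )
    return net, len(spectral), len(massdiff), len(series)


def run_pipeline(
    features: Sequence[Feature],
    spectra: Sequence[Spectrum],
    seeds: Sequence[SeedAnnotation],
    transformations: TransformationList | None = None,
    config: RunConfig = RunConfig(),
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Build all networks, merge, propagate, resolve and summarize.

    When ``outdir`` is given, the annotation table, the level summary,
    the merged graph (GraphML) and the effective configuration are
    written there.
    """
    net, n_spec, n_md, n_series = build_merged_network(
        features, spectra, transformations, config
    )
    raw = propagate(net, seeds, config.second_neighbor_min_types)
    resolved = resolve(raw)
    summary = summarize_levels(resolved)
    log.info("annotations: %d raw, %d resolved (%d features, %d multiple)",
             len(raw), len(resolved),
             len({a.feature_id for a in resolved}), summary["multiple"])
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_annotation_table(resolved, outdir / "annotations.csv")
        write_level_summary(summary, outdir / "level_summary.csv")
        write_graphml(net, outdir / "network.graphml", resolved)
        config.to_yaml(outdir / "config.yaml")
    return PipelineResult(net, raw, resolved, summary, n_spec, n_md, n_series)
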