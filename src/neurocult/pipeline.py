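"""Pipeline orchestration: simulate -> reconstruct -> metrics -> null models -> MFA.

One YAML config drives the whole run.  A single global seed is expanded
into per-stage seeds by a fixed counter scheme, so any stage can be
re-run in isolation and reproduce its output; a manifest lists every
emitted file.  Re-running the same config and seed reproduces the CSV
and JSON outputs byte for byte (the manifest records no timestamps).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__
from .metrics import (
    assortativity,
    clustering_summary,
    edge_length_exceedance,
    node_to_node_matrix,
    snapshot_series_summary,
)
from .multifractal import legendre_spectrum, mass_exponents
from .network import SpatialNetwork, read_graphml, write_graphml
from .null_models import MODEL_KINDS, compare_models
from .reconstruction import ReconstructionParams, reconstruct_image
from .synthetic import (
    CultureSpec,
    read_image,
    render_snapshot,
    sample_ground_truth,
    write_image,
)

__all__ = ["RunConfig", "RunReport", "StageError", "run_pipeline", "stage_seed"]

log = logging.getLogger("neurocult.pipeline")

_STAGES = ("simulate", "reconstruct", "metrics", "nullcompare", "mfa")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and last artifact."""

    def __init__(self, stage: str, last_artifact: str | None, cause: Exception):
        self.stage = stage
        self.last_artifact = last_artifact
        super().__init__(
            f"stage {stage!r} failed ({cause}); last valid artifact: "
            f"{last_artifact or 'none'}"
        )


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a per-stage seed from the global seed by a fixed counter."""
    idx = _STAGES.index(stage)
    return int(
        np.random.SeedSequence((int(global_seed), idx)).generate_state(1)[0]
        % (2**31 - 1)
    )


@dataclass
class RunConfig:
    """Everything one pipeline run needs, loadable from a YAML file.

    Exactly one input route applies: ``culture`` (simulate images first),
    ``images`` (reconstruct existing snapshots), or ``networks``
    (pre-built GraphML; the reconstruction stage is skipped).
    """

    out_dir: str
    seed: int = 0
    mode: str = "neuron"
    culture: dict | None = None
    images: list[str] | None = None
    networks: list[str] | None = None
    reconstruction: dict = field(default_factory=dict)
    normalized_centralities: bool = False
    null_models: dict = field(default_factory=dict)
    mfa: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("neuron", "cluster"):
            raise ValueError("mode must be 'neuron' or 'cluster'")
        routes = [
            x is not None for x in (self.culture, self.images, self.networks)
        ]
        if sum(routes) != 1:
            raise ValueError(
                "exactly one of culture/images/networks must be provided"
            )
        if not isinstance(self.seed, int):
            raise ValueError("seed must be an integer")
        for path in (self.images or []) + (self.networks or []):
            if not Path(path).exists():
                raise ValueError(f"input path does not exist: {path}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def as_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


@dataclass
class RunReport:
    """Outputs of one run: the manifest plus in-memory handles."""

    manifest: dict
    networks: list[SpatialNetwork]
    out_dir: Path


def _recon_params(cfg: RunConfig) -> ReconstructionParams:
    return ReconstructionParams(mode=cfg.mode, **cfg.reconstruction)


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute all stages in order, writing every artifact before the next.

    Reconstruction is skipped when networks are supplied directly.  Any
    stage error aborts with the stage name and the last valid artifact.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: list[str] = []
    counts: dict[str, Any] = {}
    last: str | None = None

    def emit(path: Path) -> str:
        nonlocal last
        rel = str(path.relative_to(out))
        files.append(rel)
        last = rel
        return rel

    stages_run: list[str] = []
    nets: list[SpatialNetwork] = []

    # ------------------------------------------------------------ simulate
    image_paths: list[Path] = []
    if config.culture is not None:
        try:
            stages_run.append("simulate")
            seed = stage_seed(config.seed, "simulate")
            spec = CultureSpec(**config.culture)
            truth = sample_ground_truth(spec, seed)
            img_dir = out / "images"
            img_dir.mkdir(exist_ok=True)
            for snap in range(spec.n_snapshots):
                image = render_snapshot(truth, spec, snap, seed)
                p = write_image(image, img_dir / f"snapshot_{snap:02d}.tif")
                emit(p)
                emit(p.with_suffix(p.suffix + ".json"))
                image_paths.append(p)
            truth.to_graphml(out / "ground_truth.graphml")
            emit(out / "ground_truth.graphml")
            truth.clutter_to_csv(out / "ground_truth_clutter.csv")
            emit(out / "ground_truth_clutter.csv")
            counts["simulated_somas"] = spec.n_somas
            counts["simulated_edges"] = len(truth.edges)
            log.info("simulate: %d somas, %d edges", spec.n_somas, len(truth.edges))
        except Exception as exc:
            raise StageError("simulate", last, exc) from exc
    elif config.images is not None:
        image_paths = [Path(p) for p in config.images]

    # --------------------------------------------------------- reconstruct
    net_dir = out / "networks"
    net_dir.mkdir(exist_ok=True)
    if config.networks is not None:
        nets = [read_graphml(p) for p in config.networks]
    else:
        try:
            stages_run.append("reconstruct")
            params = _recon_params(config)
            soma_counts, edge_counts, dead = [], [], []
            for snap, p in enumerate(image_paths):
                net = reconstruct_image(read_image(p), params)
                nets.append(net)
                gp = net_dir / f"network_{snap:02d}.graphml"
                write_graphml(net, gp)
                emit(gp)
                cp = net_dir / f"network_{snap:02d}_edges.csv"
                net.to_edge_csv(cp)
                emit(cp)
                soma_counts.append(net.n_nodes)
                edge_counts.append(net.n_edges)
                dead.append(net.graph.graph.get("walks_without_target", 0))
            counts["somas_per_snapshot"] = soma_counts
            counts["edges_per_snapshot"] = edge_counts
            counts["walks_without_target"] = dead
            log.info("reconstruct: %s edges per snapshot", edge_counts)
        except Exception as exc:
            raise StageError("reconstruct", last, exc) from exc

    # ------------------------------------------------------------- metrics
    try:
        stages_run.append("metrics")
        met_dir = out / "metrics"
        met_dir.mkdir(exist_ok=True)
        summary = snapshot_series_summary(nets, config.normalized_centralities)
        summary.per_node.to_csv(met_dir / "centralities.csv", index=False)
        emit(met_dir / "centralities.csv")
        summary.means.to_csv(met_dir / "centrality_trend.csv", index=False)
        emit(met_dir / "centrality_trend.csv")
        per_snap = []
        for snap, net in enumerate(nets):
            mix = node_to_node_matrix(net)
            mp = met_dir / f"mixing_matrix_{snap:02d}.csv"
            mix.to_csv(mp)
            emit(mp)
            entry: dict[str, Any] = {
                "snapshot": snap,
                "time_h": net.time_h,
                "n_nodes": net.n_nodes,
                "n_edges": net.n_edges,
                "mixing_peaks": mix.peaks,
            }
            entry.update(clustering_summary(net).as_dict())
            if net.n_edges:
                entry["assortativity"] = assortativity(net)
                exc_curve = edge_length_exceedance(net)
                ep = met_dir / f"exceedance_{snap:02d}.csv"
                exc_curve.to_frame().to_csv(ep, index=False)
                emit(ep)
            per_snap.append(entry)
        with open(met_dir / "summary.json", "w") as fh:
            json.dump(per_snap, fh, indent=2, sort_keys=True, default=float)
        emit(met_dir / "summary.json")
    except StageError:
        raise
    except Exception as exc:
        raise StageError("metrics", last, exc) from exc

    # --------------------------------------------------------- nullcompare
    nm_cfg = dict(config.null_models)
    if nm_cfg.get("enabled", True) and nets:
        try:
            stages_run.append("nullcompare")
            target = nets[nm_cfg.get("snapshot", len(nets) - 1)]
            if target.n_edges:
                comparison = compare_models(
                    target.largest_component(),
                    kinds=nm_cfg.get("kinds", list(MODEL_KINDS)),
                    n_realizations=nm_cfg.get("n_realizations", 1000),
                    seed=stage_seed(config.seed, "nullcompare"),
                )
                comparison.table.to_csv(out / "model_comparison.csv", index=False)
                emit(out / "model_comparison.csv")
                with open(out / "model_comparison.json", "w") as fh:
                    json.dump(
                        {
                            "n_realizations": comparison.n_realizations,
                            "failures": comparison.failures,
                            "rows": comparison.table.to_dict("records"),
                        },
                        fh,
                        indent=2,
                        sort_keys=True,
                        default=float,
                    )
                emit(out / "model_comparison.json")
        except StageError:
            raise
        except Exception as exc:
            raise StageError("nullcompare", last, exc) from exc

    # ---------------------------------------------------------------- mfa
    mfa_cfg = dict(config.mfa)
    if mfa_cfg.get("enabled", True) and nets:
        try:
            stages_run.append("mfa")
            mfa_dir = out / "mfa"
            mfa_dir.mkdir(exist_ok=True)
            q_grid = np.arange(
                mfa_cfg.get("q_min", -10.0),
                mfa_cfg.get("q_max", 10.0) + 1e-9,
                mfa_cfg.get("q_step", 0.5),
            )
            snaps = mfa_cfg.get("snapshots")
            if snaps is None:
                snaps = sorted({0, len(nets) // 2, len(nets) - 1})
            mfa_summaries = {}
            for snap in snaps:
                net = nets[snap].largest_component()
                if net.n_edges < 4:
                    continue
                me = mass_exponents(
                    net,
                    q_grid=q_grid,
                    n_covers=mfa_cfg.get("n_covers", 20),
                    seed=stage_seed(config.seed, "mfa") + snap,
                )
                if me.degenerate:
                    mfa_summaries[str(snap)] = {"degenerate": True}
                    continue
                spectrum = legendre_spectrum(me)
                frame = me.to_frame().merge(
                    spectrum.to_frame(), on="q", how="left"
                )
                fp = mfa_dir / f"spectrum_{snap:02d}.csv"
                frame.to_csv(fp, index=False)
                emit(fp)
                mfa_summaries[str(snap)] = spectrum.summary()
            with open(mfa_dir / "summary.json", "w") as fh:
                json.dump(mfa_summaries, fh, indent=2, sort_keys=True, default=float)
            emit(mfa_dir / "summary.json")
        except StageError:
            raise
        except Exception as exc:
            raise StageError("mfa", last, exc) from exc

    # ------------------------------------------------------------ manifest
    cfg_dict = config.as_dict()
    cfg_hash = hashlib.sha256(
        json.dumps(cfg_dict, sort_keys=True, default=str).encode()
    ).hexdigest()
    manifest = {
        "version": __version__,
        "config": cfg_dict,
        "config_sha256": cfg_hash,
        "seed": config.seed,
        "stage_seeds": {s: stage_seed(config.seed, s) for s in stages_run},
        "stages": stages_run,
        "counts": counts,
        "files": files,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=float)
    return RunReport(manifest=manifest, networks=nets, out_dir=out)
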