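"""End-to-end pipeline: ingest → features → clustering → stats → flow/FTLE.

A run is driven by a :class:`PipelineConfig` (flat key-value document,
loadable from YAML), executes the stages in order with seeded randomness,
writes all tabular outputs as CSV and matrices as delimited text, and
returns a :class:`RunReport` whose manifest lists every output file with
its SHA-256 checksum.  Reruns under the same config and inputs are
byte-identical.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cluster as cl
from . import features as ft
from . import flow as fl
from .io import TrackSet, read_tracker_csv, rescale_tracks, validate_tracks
from .ppt import fit_principal_tree

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "RunReport",
    "run_pipeline",
    "summarize_flow_presence",
]


@dataclass
class PipelineConfig:
    """Effective configuration of one pipeline run.

    Flat keys mirror the config-file schema, e.g. ``cluster.resolution``
    maps to :attr:`cluster_resolution`.  The effective config is persisted
    alongside the outputs.
    """

    # io
    input_csv: str | None = None
    io_um_per_px: float = 1.0
    io_fps: float = 24.0
    io_subsample_factor: int = 2
    # features
    features_window_points: int = 20
    features_turn_threshold: float = 1.2
    # cluster
    do_cluster: bool = True
    cluster_n_neighbors: int = 15
    cluster_resolution: float = 0.05
    cluster_min_dist: float = 0.2
    cluster_embedding: bool = True
    # permutation test (run per species when >= 2 species present)
    perm_n: int = 1000
    # field / FTLE
    do_field: bool = True
    field_grid_nx: int = 30
    field_grid_ny: int = 30
    field_smoothing: float = 0.5
    do_ftle: bool = True
    ftle_n_steps: int = 20000
    ftle_dt_frames: float = 5.0
    ftle_boundary: str = "clamp_velocity_zero"
    # principal tree (fitted to the bead positions of one retained frame)
    do_ppt: bool = False
    ppt_lambda: float = 10.0
    ppt_sigma: float = 10.0
    ppt_frame: int = 0
    ppt_max_iter: int = 50
    # presence heuristic
    presence_r_min: float = 0.6
    presence_v_min: float = 2.0
    presence_f_min: float = 0.5
    presence_min_tracks: int = 5
    # run
    outdir: str = "ciliaflow_out"
    seed: int = 0

    _KEYMAP = {
        "io.input_csv": "input_csv",
        "io.um_per_px": "io_um_per_px",
        "io.fps": "io_fps",
        "io.subsample_factor": "io_subsample_factor",
        "features.window_points": "features_window_points",
        "features.turn_threshold": "features_turn_threshold",
        "cluster.enabled": "do_cluster",
        "cluster.n_neighbors": "cluster_n_neighbors",
        "cluster.resolution": "cluster_resolution",
        "cluster.min_dist": "cluster_min_dist",
        "cluster.embedding": "cluster_embedding",
        "perm.n": "perm_n",
        "field.enabled": "do_field",
        "field.grid_nx": "field_grid_nx",
        "field.grid_ny": "field_grid_ny",
        "field.smoothing": "field_smoothing",
        "ftle.enabled": "do_ftle",
        "ftle.n_steps": "ftle_n_steps",
        "ftle.dt_frames": "ftle_dt_frames",
        "ftle.boundary": "ftle_boundary",
        "ppt.enabled": "do_ppt",
        "ppt.lambda": "ppt_lambda",
        "ppt.sigma": "ppt_sigma",
        "ppt.frame": "ppt_frame",
        "ppt.max_iter": "ppt_max_iter",
        "presence.r_min": "presence_r_min",
        "presence.v_min": "presence_v_min",
        "presence.f_min": "presence_f_min",
        "presence.min_tracks": "presence_min_tracks",
        "run.outdir": "outdir",
        "run.seed": "seed",
    }

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        """Load a flat ``section.key: value`` YAML config document."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for key, value in raw.items():
            if key not in cls._KEYMAP:
                raise KeyError(f"unknown config key {key!r}")
            kwargs[cls._KEYMAP[key]] = value
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        inv = {v: k for k, v in self._KEYMAP.items()}
        flat = {inv[k]: v for k, v in asdict(self).items() if k in inv}
        with open(path, "w") as fh:
            yaml.safe_dump(flat, fh, sort_keys=True)


@dataclass
class RunReport:
    """Per-stage counts, warnings and the output manifest with checksums."""

    stage_counts: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    manifest: dict = field(default_factory=dict)  # relative path -> sha256
    wall_time_s: float = 0.0

    def verify(self, outdir: str | Path) -> bool:
        """Every manifest entry exists on disk with a matching checksum."""
        outdir = Path(outdir)
        return all(
            (outdir / rel).exists() and _sha256(outdir / rel) == digest
            for rel, digest in self.manifest.items()
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def summarize_flow_presence(
    table: ft.FeatureTable,
    r_min: float = 0.6,
    v_min: float = 2.0,
    f_min: float = 0.5,
    min_tracks: int = 5,
) -> dict:
    """Heuristic verdict on whether a recording shows directional currents.

    A track "qualifies" when its straightness (displacement / length) is at
    least ``r_min`` and its mean speed at least ``v_min`` µm/s; the verdict
    is "directional currents detected" when the qualifying fraction reaches
    ``f_min``.  Thresholds are explicit configuration; the verdict is a
    heuristic summary, not a statistical test.
    """
    if table.normalization != "raw":
        raise ValueError("presence summary needs the raw feature table")
    n = len(table)
    if n < min_tracks:
        return {"verdict": "insufficient data", "n_tracks": n}
    df = table.df
    straightness = df["displacement_length"] / np.maximum(df["track_length"], 1e-12)
    qualifies = (straightness >= r_min) & (df["mean_speed"] >= v_min)
    frac = float(qualifies.mean())
    detected = frac >= f_min
    return {
        "verdict": "directional currents detected" if detected else "no directional currents detected",
        "detected": bool(detected),
        "n_tracks": n,
        "qualifying_fraction": frac,
        "median_straightness": float(straightness.median()),
        "median_mean_speed": float(df["mean_speed"].median()),
        "thresholds": {"r_min": r_min, "v_min": v_min, "f_min": f_min},
        "heuristic": True,
    }


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.9g", lineterminator="\n")


def run_pipeline(config: PipelineConfig, tracks: TrackSet | None = None) -> RunReport:
    """Execute the configured stages in order and persist all outputs.

    ``tracks`` may be passed directly (e.g. a synthetic TrackSet); otherwise
    ``config.input_csv`` is read.  Stages disabled in the config are
    skipped; later stages not depending on them still run.  Rerunning with
    the same config and inputs reproduces identical outputs.
    """
    t0 = time.perf_counter()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport()
    outputs: list[Path] = []

    # ingest ---------------------------------------------------------------
    if tracks is None:
        if config.input_csv is None:
            raise ValueError("config.input_csv is required when no TrackSet is given")
        tracks = read_tracker_csv(
            config.input_csv,
            fps=config.io_fps,
            subsample_factor=config.io_subsample_factor,
        )
        if config.io_um_per_px != 1.0:
            tracks = rescale_tracks(tracks, config.io_um_per_px)
    vrep = validate_tracks(tracks)
    report.stage_counts["ingest_tracks"] = len(tracks)
    for issue in vrep.issues:
        report.warnings.append(f"validate: {issue}")
    logger.info("ingest: %d tracks, %d validation issue(s)", len(tracks), len(vrep.issues))

    # features -------------------------------------------------------------
    fparams = ft.FeatureParams(
        window_points=config.features_window_points,
        sinuosity_turn_threshold=config.features_turn_threshold,
    )
    table = ft.feature_table(tracks, fparams)
    report.stage_counts["feature_rows"] = len(table)
    for exc in table.flags.get("excluded", []):
        report.warnings.append(f"features: excluded {exc}")
    fcsv = outdir / "features.csv"
    _write_csv(table.df, fcsv)
    outputs.append(fcsv)

    ztable = ft.zscore_features(table) if len(table) >= 2 else None
    presence = summarize_flow_presence(
        table,
        r_min=config.presence_r_min,
        v_min=config.presence_v_min,
        f_min=config.presence_f_min,
        min_tracks=config.presence_min_tracks,
    )
    ppath = outdir / "presence.yaml"
    with open(ppath, "w") as fh:
        yaml.safe_dump(presence, fh, sort_keys=True)
    outputs.append(ppath)
    logger.info("features: %d rows; presence: %s", len(table), presence["verdict"])

    # clustering -----------------------------------------------------------
    if config.do_cluster and ztable is not None and len(ztable) >= config.cluster_n_neighbors + 1:
        clu = cl.TrackClusterer(
            n_neighbors=config.cluster_n_neighbors,
            resolution=config.cluster_resolution,
            min_dist=config.cluster_min_dist,
            compute_embedding=config.cluster_embedding,
            random_state=config.seed,
        ).fit(ztable)
        labels = clu.labels_
        ldf = pd.DataFrame({"track_id": table.df["track_id"], "cluster": labels})
        lcsv = outdir / "labels.csv"
        _write_csv(ldf, lcsv)
        outputs.append(lcsv)
        report.stage_counts["clusters"] = int(labels.max())
        if clu.embedding_ is not None:
            edf = pd.DataFrame(
                {
                    "track_id": table.df["track_id"],
                    "u1": clu.embedding_[:, 0],
                    "u2": clu.embedding_[:, 1],
                }
            )
            ecsv = outdir / "embedding.csv"
            _write_csv(edf, ecsv)
            outputs.append(ecsv)

        species = table.df["species"].fillna("unknown").to_numpy()
        if len(pd.unique(species)) >= 2:
            comp = cl.cluster_composition(labels, species)
            ccsv = outdir / "composition.csv"
            comp.to_csv(ccsv, float_format="%.9g", lineterminator="\n")
            outputs.append(ccsv)
            dmat = cl.composition_distance_matrix(comp)
            dcsv = outdir / "composition_distance.csv"
            dmat.to_csv(dcsv, float_format="%.9g", lineterminator="\n")
            outputs.append(dcsv)
            perm_rows = []
            for k, sp in enumerate(comp.index):
                res = cl.permutation_proportion_test(
                    labels,
                    species == sp,
                    cl.PermutationParams(n_permutations=config.perm_n, seed=config.seed + k),
                )
                res.insert(0, "species", sp)
                perm_rows.append(res)
            pcsv = outdir / "permutation_tests.csv"
            _write_csv(pd.concat(perm_rows, ignore_index=True), pcsv)
            outputs.append(pcsv)
        tt = cl.cluster_feature_ttests(ztable, labels)
        tcsv = outdir / "cluster_ttests.csv"
        _write_csv(tt, tcsv)
        outputs.append(tcsv)
    elif config.do_cluster:
        report.warnings.append("cluster: skipped (too few feature rows)")

    # vector field / FTLE ----------------------------------------------------
    if config.do_field:
        fieldest = fl.fit_grid_vector_field(
            tracks,
            grid_nx=config.field_grid_nx,
            grid_ny=config.field_grid_ny,
            smoothing_weight=config.field_smoothing,
        )
        fmat = outdir / "vector_field.txt"
        fieldest.write_matrix_text(fmat)
        outputs.append(fmat)
        flong = outdir / "vector_field.csv"
        _write_csv(fieldest.to_long_dataframe(), flong)
        outputs.append(flong)
        report.stage_counts["field_observations"] = fieldest.n_observations_

        if config.do_ftle:
            fparams_ftle = fl.FTLEParams(
                n_steps=config.ftle_n_steps,
                dt_frames=config.ftle_dt_frames,
                boundary_mode=config.ftle_boundary,
            )
            ftle = fl.compute_ftle(fieldest, fparams_ftle)
            fcsv2 = outdir / "ftle.csv"
            _write_csv(ftle.to_long_dataframe(), fcsv2)
            outputs.append(fcsv2)
            report.stage_counts["ftle_nodes"] = int(ftle.values.size)

    # principal tree ---------------------------------------------------------
    if config.do_ppt:
        pts = np.vstack(
            [t.xy[t.frames == config.ppt_frame] for t in tracks if (t.frames == config.ppt_frame).any()]
        )
        if len(pts) >= 2:
            tree = fit_principal_tree(
                pts,
                lam=config.ppt_lambda,
                sigma=config.ppt_sigma,
                max_iter=config.ppt_max_iter,
                random_state=config.seed,
            )
            ndf = pd.DataFrame(tree.nodes_, columns=["x", "y"])
            ncsv = outdir / "ppt_nodes.csv"
            _write_csv(ndf, ncsv)
            outputs.append(ncsv)
            edf2 = pd.DataFrame(tree.edges_, columns=["node_a", "node_b"])
            ecsv2 = outdir / "ppt_edges.csv"
            _write_csv(edf2, ecsv2)
            outputs.append(ecsv2)
            report.stage_counts["ppt_nodes"] = len(tree.nodes_)
        else:
            report.warnings.append(f"ppt: fewer than 2 points at frame {config.ppt_frame}")

    # effective config + manifest -------------------------------------------
    cfgpath = outdir / "config.yaml"
    config.to_yaml(cfgpath)
    outputs.append(cfgpath)
    report.manifest = {p.name: _sha256(p) for p in outputs}
    report.wall_time_s = time.perf_counter() - t0
    with open(outdir / "report.yaml", "w") as fh:
        yaml.safe_dump(
            {
                "stage_counts": report.stage_counts,
                "warnings": report.warnings,
                "manifest": report.manifest,
                "wall_time_s": report.wall_time_s,
            },
            fh,
            sort_keys=True,
        )
    return report
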