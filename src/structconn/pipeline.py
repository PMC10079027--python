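"""End-to-end pipeline: simulate -> build -> average -> restrict/normalize
-> centrality -> topology -> report files.

A :class:`PipelineConfig` fully determines a run (all randomness is seeded),
so rerunning with the same config reproduces every output file byte for
byte.  The pipeline emits the four connectome variants — extended and
restricted, each raw and volume-normalized — with one ranking table per
centrality measure per variant, a global-topology summary table, and a
provenance JSON (config hash, seeds, library versions, discard tallies).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__, build, centrality, io, synthetic, topology
from .synthetic import VolumeSpec

__all__ = ["PipelineConfig", "run_pipeline", "VARIANTS"]

VARIANTS = ("extended_raw", "extended_volnorm", "restricted_raw", "restricted_volnorm")

log = logging.getLogger("structconn")


@dataclass(frozen=True)
class PipelineConfig:
    """Serializable configuration of a full synthetic-analysis run."""

    seed: int = 0
    n_regions: int = 10
    n_hubs: int = 1
    volume_median: float = 3000.0
    volume_sigma: float = 0.4
    hub_volume_multiplier: float = 3.0
    w_in: float = 2.0
    w_out: float = 1.0
    hub_boost: float = 3.0
    grid_shape: tuple[int, int, int] = (16, 16, 16)
    n_subjects: int = 4
    n_runs: int = 2
    n_streamlines: int = 2000
    subject_noise_sd: float = 0.2
    remove_labels: tuple[int, ...] | None = None  # default: the hub labels
    restriction_mode: str = "endpoint_filter"
    measures: tuple[str, ...] = centrality.MEASURES
    n_restarts: int = 10
    top_k: int = 10
    save_endpoints: bool = False
    out_dir: str = "structconn_out"
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        d["measures"] = list(self.measures)
        d["remove_labels"] = None if self.remove_labels is None else list(self.remove_labels)
        return d

    def config_hash(self) -> str:
        """Hash of the result-determining fields (where outputs go and how
        verbosely we log does not change what is computed)."""
        d = self.to_dict()
        for key in ("out_dir", "log_level"):
            d.pop(key, None)
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "grid_shape" in d:
            d["grid_shape"] = tuple(d["grid_shape"])
        if "measures" in d:
            d["measures"] = tuple(d["measures"])
        if d.get("remove_labels") is not None:
            d["remove_labels"] = tuple(d["remove_labels"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class ReportBundle:
    """In-memory handles to everything a pipeline run produced."""

    config: PipelineConfig
    parcellation: object
    subject_matrices: dict[str, list]          # variant -> per-subject matrices
    ensemble_stats: dict[str, object]          # variant -> EnsembleStats
    rankings: dict[str, dict[str, object]]     # variant -> measure -> RankingTable
    topology_points: object = None
    topology_centroids: object = None
    discard_tallies: dict = field(default_factory=dict)
    out_dir: Path | None = None


def _stage(name: str):
    def deco(fn):
        def wrapped(*a, **k):
            try:
                return fn(*a, **k)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
        return wrapped
    return deco


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute the full synthetic pipeline and write the report bundle."""
    logging.basicConfig(stream=sys.stderr, level=config.log_level)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    s_parc, s_vol, s_ens, s_topo = (int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(4))

    # -- simulate ----------------------------------------------------------
    simulate = _stage("simulate")(_simulate)
    parc, label_vol, gt, records = simulate(config, s_parc, s_vol, s_ens)
    log.info("simulated %d regions, %d record sets", parc.n_regions, len(records))

    # -- build the four variants ------------------------------------------
    build_variants = _stage("build")(_build_variants)
    subject_matrices, tallies = build_variants(config, parc, label_vol, gt, records)

    stats = {
        v: build.average_subjects(ms, n_runs=config.n_runs)
        for v, ms in subject_matrices.items()
    }

    # -- centrality rankings ----------------------------------------------
    rank = _stage("centrality")(_rankings)
    rankings = rank(config, subject_matrices)

    # -- topology ----------------------------------------------------------
    topo = _stage("topology")(topology.integration_segregation_summary)
    points, centroids = topo(subject_matrices, seed=s_topo, n_restarts=config.n_restarts)

    # -- report ------------------------------------------------------------
    write = _stage("report")(_write_report)
    write(config, out_dir, parc, label_vol, records, stats, rankings,
          points, centroids, tallies)

    return ReportBundle(
        config=config,
        parcellation=parc,
        subject_matrices=subject_matrices,
        ensemble_stats=stats,
        rankings=rankings,
        topology_points=points,
        topology_centroids=centroids,
        discard_tallies=tallies,
        out_dir=out_dir,
    )


def _simulate(config: PipelineConfig, s_parc: int, s_vol: int, s_ens: int):
    parc = synthetic.make_parcellation(
        config.n_regions,
        config.n_hubs,
        VolumeSpec(config.volume_median, config.volume_sigma, config.hub_volume_multiplier),
        seed=s_parc,
    )
    label_vol = synthetic.make_label_volume(parc, config.grid_shape, seed=s_vol)
    gt = synthetic.make_ground_truth_matrix(
        parc, config.w_in, config.w_out, config.hub_boost
    )
    records = synthetic.generate_ensemble(
        gt, label_vol, config.n_subjects, config.n_runs, config.n_streamlines,
        config.subject_noise_sd, seed=s_ens,
    )
    return parc, label_vol, gt, records


def _build_variants(config, parc, label_vol, gt, records):
    remove = (
        set(config.remove_labels)
        if config.remove_labels is not None
        else set(int(x) for x in parc.hub_labels)
    )
    keep = [int(x) for x in parc.labels if int(x) not in remove]
    if not keep:
        raise ValueError("restriction removes every structure")
    volumes = parc.volume_of()

    per_subject: dict[str, list] = {v: [] for v in VARIANTS}
    tallies: dict[str, dict[str, int]] = {"extended": {}, "restricted": {}}
    by_subject: dict[int, list] = {}
    for rs in records:
        by_subject.setdefault(rs.subject_id, []).append(rs)

    for subj in sorted(by_subject):
        ext_runs, res_runs = [], []
        for rs in sorted(by_subject[subj], key=lambda r: r.run_id):
            res_ext = build.build_matrix(rs, label_vol, parc)
            res_res = build.restrict(
                rs, keep, config.restriction_mode,
                label_volume=label_vol, parcellation=parc,
            )
            ext_runs.append(res_ext.matrix)
            res_runs.append(res_res.matrix)
            for side, res in (("extended", res_ext), ("restricted", res_res)):
                for k, v in res.discarded.items():
                    tallies[side][k] = tallies[side].get(k, 0) + v
        ext = build.average_runs(ext_runs)
        res = build.average_runs(res_runs)
        per_subject["extended_raw"].append(ext)
        per_subject["restricted_raw"].append(res)
        per_subject["extended_volnorm"].append(build.volume_normalize(ext, volumes))
        per_subject["restricted_volnorm"].append(build.volume_normalize(res, volumes))
    return per_subject, tallies


def _rankings(config, subject_matrices):
    out: dict[str, dict[str, centrality.RankingTable]] = {}
    for variant, mats in subject_matrices.items():
        out[variant] = {}
        for measure in config.measures:
            vectors = centrality.per_subject_centralities(mats, measure)
            out[variant][measure] = centrality.rank_structures(vectors)
    return out


def _write_report(config, out_dir, parc, label_vol, records, stats, rankings,
                  points, centroids, tallies):
    parc.to_csv(out_dir / "parcellation.csv")
    io.write_label_volume(label_vol, out_dir / "labels.nii")
    if config.save_endpoints:
        io.write_endpoints(records, out_dir / "endpoints.tsv")

    provenance = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "discard_tallies": tallies,
        "versions": _versions(),
    }
    for variant, st in stats.items():
        io.write_matrix(st.mean_matrix, out_dir / f"matrix_{variant}.tsv", provenance)
        io.write_rankings(
            list(rankings[variant].values()), out_dir / f"ranking_{variant}.csv"
        )

    points.to_csv(out_dir / "topology_points.csv", index=False)
    centroids.to_csv(out_dir / "topology_centroids.csv", index=False)

    # Fig-3-style export: top-k nodes by degree and their strongest edges
    ext = stats["extended_raw"].mean_matrix
    deg = centrality.degree_centrality(ext)
    table = centrality.rank_structures([deg])
    table.rows.head(config.top_k).to_csv(out_dir / "top_nodes.csv", index=False)
    _top_edges(ext, config.top_k).to_csv(out_dir / "top_edges.csv", index=False)

    with open(out_dir / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)
        fh.write("\n")
    log.info("report written to %s", out_dir)


def _top_edges(matrix, k: int):
    import pandas as pd

    w = matrix.weights
    iu, ju = np.triu_indices(matrix.n_nodes, 1)
    order = np.argsort(-w[iu, ju], kind="stable")[: 2 * k]
    return pd.DataFrame(
        {
            "source": [matrix.node_names[iu[o]] for o in order],
            "target": [matrix.node_names[ju[o]] for o in order],
            "weight": [w[iu[o], ju[o]] for o in order],
        }
    )


def _versions() -> dict[str, str]:
    import networkx
    import nibabel
    import pandas
    import scipy

    return {
        "structconn": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
        "networkx": networkx.__version__,
        "nibabel": nibabel.__version__,
    }
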