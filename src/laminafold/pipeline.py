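"""End-to-end demo pipeline and run configuration.

Sequence: synthetic inputs -> DamID LAD calling -> bulk polymer
equilibration -> NE attachment -> ensemble quantification, with parallel
branches for image volumetrics and TAD co-expression.  Every stage draws
its random stream from the master seed through a fixed counter scheme, so
a configuration reproduces its outputs bit-identically; the manifest lists
every artifact with a sha256 checksum.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Dict

import numpy as np

from . import io as lfio
from . import metrics, synth
from .coexpr import classify_ubiquity, tad_census
from .damid import call_lads, classify_ne_affinity
from .fishq import distance_to_lamin, intermingling_fraction, jaccard, segment_fish
from .polymer import PolymerSpec, SimParams, attach_ne, run_equilibration


@dataclass
class RunConfig:
    """Parameters of one demo pipeline run (JSON round-trippable)."""

    master_seed: int = 0
    n_beads: int = 40
    n_types: int = 3
    n_steps_equil: int = 30_000
    n_steps_ne: int = 15_000
    sample_every: int = 1_000
    equil_burnin: int = 5_000
    e_int: float = 5.0
    e_ne: float = 1.2
    ne_radius: float = 40.0
    lad_noise_scale: float = 0.3
    image_shape: tuple = (24, 72, 72)
    n_genes: int = 30
    n_samples: int = 60
    version: str = "laminafold-0.1.0"

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["image_shape"] = list(d["image_shape"])
        return json.dumps(d, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        d["image_shape"] = tuple(d.get("image_shape", (24, 72, 72)))
        return cls(**d)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def _stage_seed(master: int, stage: int) -> int:
    """Stage stream k: independent of execution order of other stages."""
    return int(np.random.SeedSequence([int(master) & 0x7FFFFFFF, stage])
               .generate_state(1)[0] & 0x7FFFFFFF)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception, partial_manifest: dict):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.partial_manifest = partial_manifest


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Run the demo pipeline; returns the manifest dict (also written to
    ``manifest.json``).  Timings go to ``timings.json`` which is excluded
    from the checksum list."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(config.to_json())
    artifacts: Dict[str, str] = {"config.json": _sha256(out / "config.json")}
    timings = {}
    stage = "init"

    def _finish_stage(name, t0):
        timings[name] = round(time.perf_counter() - t0, 3)

    try:
        # --- stage 0: synthetic DamID + LAD calling --------------------
        stage = "damid_lads"
        t0 = time.perf_counter()
        n = config.n_beads
        lad_true = [(n // 8, n // 8 + n // 5), (n // 2, n // 2 + n // 4)]
        track, truth = synth.make_damid_track(
            n, lad_true, noise_scale=config.lad_noise_scale,
            seed=_stage_seed(config.master_seed, 0))
        seg = call_lads(track, seed=_stage_seed(config.master_seed, 0))
        lfio.write_bedgraph(
            _track_frame(track), out / "damid_log2.bedgraph")
        _write_lads(seg, track, out / "lads.bed")
        _finish_stage(stage, t0)

        # --- stage 1: polymer spec + bulk equilibration ----------------
        stage = "simulate_bulk"
        t0 = time.perf_counter()
        spec0, _ = synth.make_polymer_spec(
            n, config.n_types, seed=_stage_seed(config.master_seed, 1))
        spec = PolymerSpec(spec0.type_of_bead, classify_ne_affinity(track),
                           spec0.chrom, spec0.start, spec0.bin_size)
        params = SimParams(
            e_int=config.e_int, e_ne=config.e_ne, ne_radius=config.ne_radius,
            n_steps_equil=config.n_steps_equil, n_steps_ne=config.n_steps_ne,
            sample_every=config.sample_every, equil_burnin=config.equil_burnin,
            seed=_stage_seed(config.master_seed, 1))
        lfio.write_polymer_spec_tsv(spec, out / "polymer_spec.tsv")
        traj_bulk = run_equilibration(spec, params)
        lfio.write_trajectory_xyz(traj_bulk, out / "trajectory_bulk.xyz")
        _finish_stage(stage, t0)

        # --- stage 2: NE phase ----------------------------------------
        stage = "attach_ne"
        t0 = time.perf_counter()
        traj_ne = attach_ne(traj_bulk.final, spec, params)
        lfio.write_trajectory_xyz(traj_ne, out / "trajectory_ne.xyz")
        _finish_stage(stage, t0)

        # --- stage 3: ensemble metrics --------------------------------
        stage = "ensemble_metrics"
        t0 = time.perf_counter()
        cm_bulk = metrics.contact_map([traj_bulk])
        cm_ne = metrics.contact_map([traj_ne])
        lfio.write_contact_map_tsv(cm_bulk, out / "contact_map_bulk.tsv")
        lfio.write_contact_map_tsv(cm_ne, out / "contact_map_ne.tsv")
        lfio.write_contact_map_tsv(metrics.subtraction_map(cm_ne, cm_bulk),
                                   out / "subtraction_map.tsv")
        half = n // 2
        last_k = min(20, traj_ne.n_frames)
        dist, _ = metrics.pairwise_distance(traj_ne, (0, half), (half, n),
                                            last_k=last_k)
        sph = metrics.sphericity(traj_ne.bead_frames[-1])
        att = spec.ne_affinity
        summary = {
            "mean_halves_distance_sigma": dist,
            "final_sphericity": sph,
            "wall_contact_fraction_attractive":
                metrics.wall_contact_fraction(traj_ne, config.ne_radius,
                                              bead_mask=att)
                if att.any() else None,
            "n_lads_called": len(seg.intervals),
        }
        (out / "metrics_summary.json").write_text(
            json.dumps(summary, indent=1, sort_keys=True))
        _finish_stage(stage, t0)

        # --- stage 4: imaging branch ----------------------------------
        stage = "fish_volumetrics"
        t0 = time.perf_counter()
        shp = tuple(config.image_shape)
        ext_z = shp[0] * 0.125
        ext_xy = shp[1] * 0.04
        c = (ext_z / 2, ext_xy / 2, ext_xy / 2)
        objs = [
            synth.ImageObject((c[0], c[1] - 0.18, c[2]), 0.30, "fish_a"),
            synth.ImageObject((c[0], c[1] + 0.18, c[2]), 0.30, "fish_b"),
        ]
        vols, vtruth = synth.make_nucleus_volume(
            shp, objects=objs, lamina_shell=(1.1, 0.15),
            seed=_stage_seed(config.master_seed, 4))
        lfio.write_tiff_volume(vols, out / "volumes", (40.0, 125.0),
                               sidecar={"truth": vtruth.to_dict()})
        sega = segment_fish(vols["fish_a"], channel="fish_a")
        segb = segment_fish(vols["fish_b"], channel="fish_b")
        fish_summary = {}
        if sega and segb:
            fish_summary = {
                "intermingling_a_in_b": intermingling_fraction(sega[0], segb[0]),
                "jaccard": jaccard(sega[0], segb[0]),
                "distance_to_lamin_um": distance_to_lamin(
                    vols["fish_a"], vols["lamin"]),
            }
        (out / "fish_summary.json").write_text(
            json.dumps(fish_summary, indent=1, sort_keys=True))
        _finish_stage(stage, t0)

        # --- stage 5: co-expression branch ----------------------------
        stage = "tad_coexpression"
        t0 = time.perf_counter()
        tads = [(i * 200_000, (i + 1) * 200_000) for i in range(5)]
        es, etruth = synth.make_expression_set(
            config.n_genes, config.n_samples, tads,
            seed=_stage_seed(config.master_seed, 5))
        ubiq = classify_ubiquity(es, median_cutoff=60.0)
        census = tad_census(es, es.tads, ubiq)
        census_out = {k: v for k, v in census.items() if k != "table"}
        census["table"].to_csv(out / "tad_census.tsv", sep="\t")
        (out / "coexpr_summary.json").write_text(
            json.dumps(census_out, indent=1, sort_keys=True))
        _finish_stage(stage, t0)

    except Exception as exc:
        for p in sorted(out.rglob("*")):
            if p.is_file() and p.name not in ("manifest.json", "timings.json"):
                artifacts[str(p.relative_to(out))] = _sha256(p)
        raise StageFailure(stage, exc, artifacts) from exc

    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name not in ("manifest.json", "timings.json"):
            artifacts[str(p.relative_to(out))] = _sha256(p)
    manifest = {
        "config_hash": config.config_hash(),
        "master_seed": config.master_seed,
        "version": config.version,
        "artifacts": dict(sorted(artifacts.items())),
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True))
    (out / "timings.json").write_text(
        json.dumps(timings, indent=1, sort_keys=True))
    return manifest


def _track_frame(track):
    import pandas as pd
    rows = []
    for i, v in enumerate(track.values):
        s, e = track.bin_interval(i)
        if np.isfinite(v):
            rows.append(dict(chrom=track.chrom, start=s, end=e, value=v))
    return pd.DataFrame(rows)


def _write_lads(seg, track, path):
    import pandas as pd
    rows = []
    for (a, b), sc in zip(seg.intervals, seg.scores):
        rows.append(dict(chrom=track.chrom,
                         start=track.start + a * track.bin_size,
                         end=track.start + b * track.bin_size,
                         name="LAD", score=round(float(sc), 4)))
    lfio.write_bed(pd.DataFrame(rows, columns=["chrom", "start", "end",
                                               "name", "score"]), path)
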