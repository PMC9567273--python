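"""Readers and writers for the plain-text interchange formats.

All genomic coordinates are 0-based half-open (BED convention).  Image
volumes travel as one TIFF stack per channel plus a JSON sidecar holding
voxel sizes and, for synthetic data, the planted ground truth.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import numpy as np
import pandas as pd
import tifffile

PathLike = Union[str, Path]


class FormatError(ValueError):
    """Malformed input line; carries the file and 1-based line number."""

    def __init__(self, path: PathLike, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path, self.lineno = str(path), lineno


def _parse_interval(path, lineno, fields, min_fields):
    if len(fields) < min_fields:
        raise FormatError(path, lineno,
                          f"expected >= {min_fields} fields, got {len(fields)}")
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise FormatError(path, lineno, f"non-integer coordinate: {exc}")
    if start < 0 or end <= start:
        raise FormatError(path, lineno,
                          f"invalid 0-based half-open interval [{start},{end})")
    return fields[0], start, end


def read_bed(path: PathLike) -> pd.DataFrame:
    """BED -> DataFrame(chrom, start, end[, name, score])."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            chrom, start, end = _parse_interval(path, lineno, f, 3)
            rec = dict(chrom=chrom, start=start, end=end)
            if len(f) > 3:
                rec["name"] = f[3]
            if len(f) > 4:
                try:
                    rec["score"] = float(f[4])
                except ValueError:
                    raise FormatError(path, lineno, f"bad score {f[4]!r}")
            rows.append(rec)
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score"]
                        ).dropna(axis=1, how="all") if rows else \
        pd.DataFrame(columns=["chrom", "start", "end"])


def write_bed(df: pd.DataFrame, path: PathLike) -> None:
    cols = [c for c in ("chrom", "start", "end", "name", "score") if c in df]
    with open(path, "w") as fh:
        for row in df[cols].itertuples(index=False):
            fh.write("\t".join(str(v) for v in row) + "\n")


def read_bedgraph(path: PathLike) -> pd.DataFrame:
    """bedGraph -> DataFrame(chrom, start, end, value)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            chrom, start, end = _parse_interval(path, lineno, f, 4)
            try:
                val = float(f[3])
            except ValueError:
                raise FormatError(path, lineno, f"bad value {f[3]!r}")
            rows.append(dict(chrom=chrom, start=start, end=end, value=val))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


def write_bedgraph(df: pd.DataFrame, path: PathLike) -> None:
    with open(path, "w") as fh:
        for row in df[["chrom", "start", "end", "value"]].itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.value:.6g}\n")


def read_tsv_matrix(path: PathLike) -> pd.DataFrame:
    """TSV with a header row and an index column -> DataFrame."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_tsv_matrix(df: pd.DataFrame, path: PathLike,
                     float_format: str = "%.6g") -> None:
    df.to_csv(path, sep="\t", float_format=float_format)


def write_tiff_volume(volumes: Dict[str, np.ndarray], directory: PathLike,
                      voxel_size_nm: Tuple[float, float],
                      sidecar: Optional[dict] = None,
                      stem: str = "volume") -> List[Path]:
    """One multi-page TIFF per channel plus a JSON sidecar with voxel sizes.

    Written without datetime metadata so identical inputs give identical
    bytes.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, vol in volumes.items():
        p = directory / f"{stem}_{name}.tif"
        tifffile.imwrite(p, np.asarray(vol, dtype=np.float32))
        paths.append(p)
    meta = {"voxel_size_nm": list(voxel_size_nm),
            "channels": sorted(volumes)}
    if sidecar:
        meta.update(sidecar)
    sp = directory / f"{stem}.json"
    sp.write_text(json.dumps(meta, indent=1, sort_keys=True, default=float))
    paths.append(sp)
    return paths


def read_tiff_volume(directory: PathLike, stem: str = "volume"
                     ) -> Tuple[Dict[str, np.ndarray], dict]:
    directory = Path(directory)
    meta = json.loads((directory / f"{stem}.json").read_text())
    vols = {name: tifffile.imread(directory / f"{stem}_{name}.tif")
            for name in meta["channels"]}
    return vols, meta


def write_polymer_spec_tsv(spec, path: PathLike) -> None:
    """PolymerSpec -> TSV (bead_index, type_id, ne_affinity)."""
    with open(path, "w") as fh:
        fh.write("bead_index\ttype_id\tne_affinity\n")
        for i, (t, a) in enumerate(zip(spec.type_of_bead, spec.ne_affinity)):
            fh.write(f"{i}\t{int(t)}\t{'attractive' if a else 'repulsive'}\n")


def read_polymer_spec_tsv(path: PathLike, chrom: str = "chrS", start: int = 0,
                          bin_size: int = 20_000):
    from .polymer import PolymerSpec
    df = pd.read_csv(path, sep="\t")
    for col in ("bead_index", "type_id", "ne_affinity"):
        if col not in df:
            raise FormatError(path, 1, f"missing column {col!r}")
    df = df.sort_values("bead_index")
    return PolymerSpec(df["type_id"].to_numpy(np.int64),
                       (df["ne_affinity"] == "attractive").to_numpy(),
                       chrom, start, bin_size)


def write_trajectory_xyz(traj, path: PathLike) -> None:
    """Trajectory -> XYZ-like text: frame, particle, kind, x, y, z."""
    with open(path, "w") as fh:
        fh.write("frame\tparticle\tkind\tx\ty\tz\n")
        for fi in range(traj.n_frames):
            for pi in range(traj.frames.shape[1]):
                kind = "bead" if pi < traj.n_beads else "binder"
                x, y, z = traj.frames[fi, pi]
                fh.write(f"{fi}\t{pi}\t{kind}\t{x:.5f}\t{y:.5f}\t{z:.5f}\n")


def write_contact_map_tsv(m: np.ndarray, path: PathLike) -> None:
    np.savetxt(path, np.asarray(m), delimiter="\t", fmt="%.6g")


def read_contact_map_tsv(path: PathLike) -> np.ndarray:
    return np.loadtxt(path, delimiter="\t", ndmin=2)


def write_contact_map_triplets(m: np.ndarray, path: PathLike,
                               min_value: float = 0.0) -> None:
    """Upper-triangle bin-pair triplet text (i, j, value)."""
    m = np.asarray(m)
    with open(path, "w") as fh:
        for i in range(m.shape[0]):
            for j in range(i, m.shape[1]):
                if m[i, j] > min_value:
                    fh.write(f"{i}\t{j}\t{m[i, j]:.6g}\n")


def read_contact_map_triplets(path: PathLike, n_bins: int) -> np.ndarray:
    m = np.zeros((n_bins, n_bins))
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            f = line.split()
            if len(f) != 3:
                raise FormatError(path, lineno, "expected i<TAB>j<TAB>value")
            i, j, v = int(f[0]), int(f[1]), float(f[2])
            m[i, j] = m[j, i] = v
    return m
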