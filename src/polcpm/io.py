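"""Delimited-text writers for trajectories, summaries, kymographs, and snapshots."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "write_trajectories",
    "write_summary",
    "write_kymograph",
    "write_snapshot",
    "write_dense_grids",
    "write_provenance",
]


def _ensure_dir(path: Path) -> Path:
    path.mkdir(parents=True, exist_ok=True)
    return path


def write_trajectories(out_dir, name: str, rec_arrays: dict) -> Path:
    """Per-record long-format table: t, cell, x, y, area, perim."""
    out = _ensure_dir(Path(out_dir)) / f"{name}.tsv"
    t = rec_arrays["t"]
    com = rec_arrays["com"]
    area = rec_arrays["area"]
    perim = rec_arrays["perim"]
    frames = []
    for cid in range(com.shape[1]):
        if np.all(np.isnan(area[:, cid])):
            continue
        frames.append(pd.DataFrame({
            "t": t, "cell": cid, "x": com[:, cid, 0], "y": com[:, cid, 1],
            "area": area[:, cid], "perim": perim[:, cid],
        }))
    pd.concat(frames, ignore_index=True).to_csv(out, sep="\t", index=False,
                                                float_format="%.6g")
    return out


def write_summary(out_dir, name: str, rows: list[dict],
                  drop_keys: tuple = ("msd", "lags", "omega")) -> Path:
    """Sweep summary table (one row per parameter point)."""
    out = _ensure_dir(Path(out_dir)) / f"{name}.tsv"
    slim = [{k: v for k, v in row.items() if k not in drop_keys} for row in rows]
    pd.DataFrame(slim).to_csv(out, sep="\t", index=False, float_format="%.6g")
    return out


def write_kymograph(out_dir, name: str, kymo) -> list[Path]:
    """Dense kymograph arrays with axis metadata, one TSV per field."""
    d = _ensure_dir(Path(out_dir))
    paths = []
    for field in ("density", "sigma_xx", "vx"):
        p = d / f"{name}_{field}.tsv"
        df = pd.DataFrame(getattr(kymo, field), index=kymo.times,
                          columns=np.round(kymo.x_centers, 3))
        df.index.name = "t"
        df.to_csv(p, sep="\t", float_format="%.6g")
        paths.append(p)
    return paths


def write_snapshot(out_dir, name: str, sim) -> Path:
    """Lattice snapshot: site, q, r, owner, eps (one row per site)."""
    out = _ensure_dir(Path(out_dir)) / f"{name}.tsv"
    lat = sim.lattice
    df = pd.DataFrame({
        "site": np.arange(lat.n_sites), "q": lat.q, "r": lat.r,
        "owner": sim.config.owner, "eps": sim.eps,
    })
    df.to_csv(out, sep="\t", index=False, float_format="%.6g")
    return out


def write_dense_grids(out_dir, name: str, sim) -> list[Path]:
    """Owner and eps as dense (n_rows x n_cols) delimited-text grids."""
    d = _ensure_dir(Path(out_dir))
    lat = sim.lattice
    paths = []
    for field, arr, fmt in (("owner", sim.config.owner, "%d"),
                            ("eps", sim.eps, "%.6g")):
        p = d / f"{name}_{field}.tsv"
        np.savetxt(p, arr.reshape(lat.n_rows, lat.n_cols), fmt=fmt, delimiter="\t")
        paths.append(p)
    return paths


def write_provenance(out_dir, config, seed: int) -> Path:
    """Config copy + seed + code version; round-trips through load_config."""
    from . import __version__
    out = _ensure_dir(Path(out_dir)) / "provenance.yaml"
    payload = config.to_dict()
    payload["run"]["seed"] = int(seed)
    meta = {"polcpm_version": __version__}
    out.write_text(yaml.safe_dump(payload, sort_keys=False)
                   + "# " + yaml.safe_dump(meta).strip() + "\n")
    return out
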