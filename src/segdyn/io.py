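"""Persistent outputs: history files, metadata sidecars, kymographs.

The canonical interchange is one wide TSV per recorded variable (rows =
time, columns = cell index, sentinel "NA" for pre-birth entries) plus a
``metadata.json`` sidecar echoing the config, cell birth steps and the
per-step scalar series.  An optional ``.npz`` mirror exists for speed; the
TSV files alone fully reconstruct a History.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ModelConfig
from .engine import History

__all__ = ["write_history", "read_history", "render_kymograph", "IOError_"]


class IOError_(RuntimeError):
    pass


def write_history(history: History, outdir: str | Path, fmt: str = "tsv") -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {
        "config": history.config.to_dict(),
        "birth": history.birth.tolist(),
        "psc": history.psc.astype(int).tolist(),
        "variables": list(history.variables),
        "format": fmt,
    }
    (outdir / "metadata.json").write_text(json.dumps(meta, indent=2))
    scalars = pd.DataFrame(
        {
            "t": np.arange(history.steps + 1),
            "L": history.L,
            "v_effective": history.v_effective,
            "additions": history.additions,
        }
    )
    scalars.to_csv(outdir / "scalars.tsv", sep="\t", index=False, float_format="%.17g")
    if fmt == "tsv":
        for name, mat in history.data.items():
            frame = pd.DataFrame(mat, columns=[f"c{i}" for i in range(mat.shape[1])])
            frame.insert(0, "t", np.arange(mat.shape[0]))
            # %.17g guarantees exact float64 round-trip through text
            frame.to_csv(
                outdir / f"{name}.tsv",
                sep="\t",
                index=False,
                na_rep="NA",
                float_format="%.17g",
            )
    elif fmt == "npz":
        np.savez(outdir / "history.npz", **history.data)
    else:
        raise IOError_(f"unknown history format: {fmt!r}")
    return outdir


def read_history(indir: str | Path) -> History:
    indir = Path(indir)
    meta_path = indir / "metadata.json"
    if not meta_path.exists():
        raise IOError_(f"no metadata.json in {indir}")
    meta = json.loads(meta_path.read_text())
    config = ModelConfig.from_dict(meta["config"])
    scalars = pd.read_csv(indir / "scalars.tsv", sep="\t")
    data = {}
    if meta.get("format") == "npz":
        with np.load(indir / "history.npz") as npz:
            for name in meta["variables"]:
                data[name] = npz[name]
    else:
        for name in meta["variables"]:
            frame = pd.read_csv(
                indir / f"{name}.tsv",
                sep="\t",
                na_values=["NA"],
                float_precision="round_trip",
            )
            data[name] = frame.drop(columns=["t"]).to_numpy(dtype=float)
    return History(
        data=data,
        birth=np.asarray(meta["birth"], dtype=int),
        L=scalars["L"].to_numpy(dtype=int),
        v_effective=scalars["v_effective"].to_numpy(dtype=float),
        additions=scalars["additions"].to_numpy(dtype=int),
        psc=np.asarray(meta["psc"], dtype=bool),
        config=config,
    )


def render_kymograph(
    history: History,
    variable: str,
    path: str | Path,
    overlays: bool = True,
) -> Path:
    """Write a PNG kymograph: cell index horizontal, time vertical (downward),
    pre-birth cells blanked; optional overlays for the posterior tip and the
    determination front."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .metrics import wavefront_position

    if history.steps < 1 or history.n_cells < 1:
        raise IOError_("history is empty; nothing to render")
    if variable not in history.data:
        raise IOError_(
            f"variable {variable!r} not recorded; available: {list(history.variables)}"
        )
    mat = np.ma.masked_invalid(history.data[variable])
    fig, ax = plt.subplots(figsize=(6, 6))
    im = ax.imshow(mat, aspect="auto", origin="upper", cmap="viridis", interpolation="nearest")
    if overlays:
        t_axis = np.arange(history.steps + 1)
        ax.plot(history.L - 0.5, t_axis, color="purple", lw=1.2, label="posterior tip")
        front = [wavefront_position(history.state_at(t)) - 0.5 for t in t_axis]
        ax.plot(front, t_axis, color="red", lw=1.2, label="determination front")
        ax.legend(loc="upper right", fontsize=7)
    ax.set_xlabel("cell index (anterior → posterior)")
    ax.set_ylabel("time step")
    ax.set_title(variable)
    fig.colorbar(im, ax=ax, shrink=0.8)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
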