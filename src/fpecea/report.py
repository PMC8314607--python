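"""CSV/plot output helpers for the command-line interface."""

from __future__ import annotations

import json
import platform
from datetime import datetime, timezone
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

__all__ = ["write_metadata", "tornado_plot", "ceac_plot"]


def write_metadata(outdir: Path, **extra) -> Path:
    """Record what produced the artifacts in this directory.

    Stores the parameter hash, seed, package and dependency versions, so
    every output file can be regenerated from the log alone.
    """
    from . import __version__

    meta = {
        "package": "fpecea",
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        **extra,
    }
    path = Path(outdir) / "run_metadata.json"
    with open(path, "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
    return path


def tornado_plot(frame: pd.DataFrame, path: Path, sex: str) -> Path:
    """Horizontal tornado bars of ICER spread per parameter group."""
    frame = frame.sort_values("spread")
    base = float(frame["icer_base"].iloc[0])
    fig, ax = plt.subplots(figsize=(7, 0.4 * len(frame) + 1.5))
    y = np.arange(len(frame))
    lo = np.minimum(frame["icer_low"], frame["icer_high"]) - base
    width = np.abs(frame["icer_high"] - frame["icer_low"])
    ax.barh(y, width, left=lo + base, color="#4878a8")
    ax.axvline(base, color="k", lw=1)
    ax.set_yticks(y)
    ax.set_yticklabels(frame["parameter"])
    ax.set_xlabel("ICER (€ per avoided hip fracture)")
    ax.set_title(f"One-way sensitivity, {sex}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def ceac_plot(curves: dict[str, pd.DataFrame], path: Path) -> Path:
    """Cost-effectiveness acceptability curve(s), one line per label."""
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for label, frame in curves.items():
        ax.plot(frame["wtp"] / 1000.0, frame["prob_cost_effective"], label=label)
    ax.set_xlabel("Willingness to pay (1000 € per avoided hip fracture)")
    ax.set_ylabel("Probability cost-effective")
    ax.set_ylim(0, 1)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
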