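"""SVG plots of thickness distributions and thickness-stability scatter."""

from __future__ import annotations

from pathlib import Path

from .report import StudyRecord
from .thickness import ThicknessDistribution


def plot_thickness_distribution(
    dists: dict[str, ThicknessDistribution], path: str | Path
) -> None:
    """Volume-fraction vs thickness class for one or more labelled samples."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    for label, dist in dists.items():
        frac = dist.class_volume / dist.total_volume
        ax.plot(dist.class_diameter, frac, marker="o", ms=3, label=label)
    ax.set_xlabel("material thickness (µm)")
    ax.set_ylabel("volume fraction")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, format="svg")
    plt.close(fig)


def plot_thickness_vs_half_life(
    records: list[StudyRecord], window: str, path: str | Path
) -> None:
    """Half-life vs thickness mode; sub-resolution samples are omitted."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    for rec in records:
        if not rec.numeric_thickness or window not in rec.t_half_days:
            continue
        ax.scatter(rec.thickness_mode_um, rec.t_half_days[window], label=rec.sample_id, s=20)
    ax.set_xlabel("material thickness mode (µm)")
    ax.set_ylabel(f"half-life {window} (days)")
    fig.tight_layout()
    fig.savefig(path, format="svg")
    plt.close(fig)
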