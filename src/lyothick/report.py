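"""Joining microstructure and stability: correlation stage and pipeline driver.

Each study sample contributes a :class:`StudyRecord` (thickness summary +
windowed half-lives); :func:`correlate_thickness_stability` computes the
thickness-stability association (Pearson r, Spearman rho, least-squares
line) per storage group.  Samples whose structure is below the tomographic
resolution carry a sentinel instead of a numeric thickness; they are
excluded from the numeric association and counted separately.  No p-values
are emitted: group sizes in this kind of study are a handful of samples,
so inference would be decorative.

:func:`run_pipeline` drives segment -> thickness -> viability -> correlate
from a TOML config (or an equivalent dict) and writes per-sample
distribution CSVs, a half-life CSV, an association CSV and a summary JSON.
Everything is deterministic given the config and its seeds.
"""

from __future__ import annotations

import json
import math
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
from scipy import stats

from . import phantoms, preprocess, thickness as thick, viability as viab
from .volumes import BinaryVolume

__all__ = [
    "SUB_RESOLUTION",
    "StudyRecord",
    "AssociationResult",
    "correlate_thickness_stability",
    "run_pipeline",
]

#: Sentinel for structures finer than the tomographic resolution.
SUB_RESOLUTION = "sub-resolution"


@dataclass
class StudyRecord:
    """One sample: structural summary joined with its stability estimates."""

    sample_id: str
    thickness_mode_um: float | str
    d_vol_um: float | str
    t_half_days: dict[str, float] = field(default_factory=dict)
    annealing_protocol: str = ""
    storage: str = ""

    def __post_init__(self) -> None:
        for v in (self.thickness_mode_um, self.d_vol_um):
            if isinstance(v, str) and v != SUB_RESOLUTION:
                raise ValueError(f"non-numeric thickness must be the {SUB_RESOLUTION!r} sentinel")
            if not isinstance(v, str) and not v > 0:
                raise ValueError(f"thickness values must be positive, got {v}")
        if not self.t_half_days:
            raise ValueError("at least one half-life estimate is required")

    @property
    def numeric_thickness(self) -> bool:
        return not isinstance(self.thickness_mode_um, str)


@dataclass
class AssociationResult:
    """Thickness-stability association within one group.

    ``pearson_r`` / ``spearman_rho`` are NaN (with ``undefined`` flag) when
    fewer than three numeric records exist or either variable has zero
    variance -- never silently.
    """

    grouping: str
    window: str
    n: int
    pearson_r: float
    spearman_rho: float
    slope_days_per_um: float
    intercept_days: float
    n_excluded_sub_resolution: int = 0
    flags: tuple[str, ...] = ()


def _associate(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float, tuple[str, ...]]:
    if len(x) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return math.nan, math.nan, math.nan, math.nan, ("undefined",)
    pear = float(stats.pearsonr(x, y).statistic)
    spear = float(stats.spearmanr(x, y).statistic)
    fit = stats.linregress(x, y)
    return pear, spear, float(fit.slope), float(fit.intercept), ()


def correlate_thickness_stability(
    records: list[StudyRecord], group_by: str | None = "storage"
) -> list[AssociationResult]:
    """Pearson/Spearman association of half-life vs thickness mode per group.

    ``group_by='storage'`` groups records by their storage label (e.g.
    canister vs vacuum bag); ``None`` pools everything.  One result per
    (group, half-life window).  Sub-resolution records are excluded and
    counted.  All-sentinel input is an error.
    """
    if group_by not in (None, "storage"):
        raise ValueError(f"group_by must be 'storage' or None, got {group_by!r}")
    if not any(r.numeric_thickness for r in records):
        raise ValueError("all records carry the sub-resolution sentinel; nothing to correlate")

    groups: dict[str, list[StudyRecord]] = {}
    for r in records:
        key = r.storage if group_by == "storage" else "all"
        groups.setdefault(key, []).append(r)

    results = []
    for key in sorted(groups):
        recs = groups[key]
        numeric = [r for r in recs if r.numeric_thickness]
        n_excl = len(recs) - len(numeric)
        windows = sorted({w for r in numeric for w in r.t_half_days})
        for window in windows:
            pairs = [
                (float(r.thickness_mode_um), r.t_half_days[window])
                for r in numeric
                if window in r.t_half_days and math.isfinite(r.t_half_days[window])
            ]
            x = np.array([p[0] for p in pairs])
            y = np.array([p[1] for p in pairs])
            pear, spear, slope, intercept, flags = _associate(x, y)
            results.append(
                AssociationResult(
                    grouping=key,
                    window=window,
                    n=len(pairs),
                    pearson_r=pear,
                    spearman_rho=spear,
                    slope_days_per_um=slope,
                    intercept_days=intercept,
                    n_excluded_sub_resolution=n_excl,
                    flags=flags,
                )
            )
    return results


# ---------------------------------------------------------------------------
# pipeline driver


def _load_config(config: str | Path | dict) -> dict:
    if isinstance(config, dict):
        return config
    with open(config, "rb") as fh:
        return tomllib.load(fh)


def _phantom_mask(sample: dict) -> BinaryVolume:
    ph = sample["phantom"]
    spec = phantoms.PhantomSpec(
        geometry=ph["geometry"],
        wall_um=ph["wall_um"],
        spacing_um=ph["spacing_um"],
        voxel_um=ph["voxel_um"],
        shape_voxels=tuple(ph["shape"]),
        seed=int(ph.get("seed", 0)),
        allow_sub_voxel=bool(ph.get("allow_sub_voxel", False)),
    )
    if spec.geometry == "parallel_plates":
        return phantoms.make_parallel_plate_phantom(spec)
    if spec.geometry == "radial_lamellae":
        return phantoms.make_radial_lamellae_phantom(spec, n_sheets=int(ph.get("n_sheets", 6)))
    return phantoms.make_spherical_pore_phantom(spec, target_porosity=float(ph["target_porosity"]))


def _sample_mask(sample: dict, seg_cfg: dict) -> tuple[BinaryVolume, dict]:
    """Resolve a sample to a segmented mask, recording the stages applied."""
    log: dict[str, Any] = {}
    if "volume" in sample:
        vol = preprocess.read_volume(sample["volume"], voxel_um=sample.get("voxel_um"))
        log["source"] = str(sample["volume"])
    elif "phantom" in sample:
        mask = _phantom_mask(sample)
        log["source"] = f"phantom:{sample['phantom']['geometry']}"
        if "render" not in sample:
            log["segmentation"] = "none (ground-truth mask)"
            return mask, log
        rnd = sample["render"]
        vol = phantoms.render_greyscale(
            mask,
            phantoms.RenderSpec(
                material_level=float(rnd.get("material_level", 200.0)),
                pore_level=float(rnd.get("pore_level", 20.0)),
                noise_sd=float(rnd.get("noise_sd", 0.0)),
                blur_sigma_voxels=float(rnd.get("blur_sigma_voxels", 0.0)),
                seed=int(rnd.get("seed", 0)),
            ),
        )
    else:
        raise ValueError(f"sample {sample.get('id')} needs a 'volume' path or a 'phantom' spec")

    window = int(seg_cfg.get("median_window", 4))
    if window > 1:
        vol = preprocess.median_filter_3d(vol, window=window)
    seg = preprocess.threshold_volume(
        vol,
        method=seg_cfg.get("threshold", "otsu"),
        manual_value=seg_cfg.get("manual_value"),
        material_is=seg_cfg.get("material_is", "bright"),
    )
    log["segmentation"] = {
        "median_window": window,
        "threshold": seg.threshold_used,
        "material_fraction": seg.material_fraction,
    }
    return seg, log


def _sample_series(sample: dict, base_dir: Path) -> viab.ViabilitySeries:
    if "viability_csv" in sample:
        path = Path(sample["viability_csv"])
        if not path.is_absolute():
            path = base_dir / path
        series = viab.read_viability_csv(path)
        if len(series) != 1:
            raise ValueError(
                f"sample {sample.get('id')}: viability CSV must hold exactly one "
                f"(batch, condition) series, found {len(series)}"
            )
        return series[0]
    if "decay" in sample:
        d = sample["decay"]
        return phantoms.simulate_viability_series(
            phantoms.DecaySpec(
                c0=float(d.get("c0", 1e9)),
                half_life_days=float(d["half_life_days"]),
                timepoints_days=tuple(d.get("timepoints_days", (0.0, 7.0, 14.0, 28.0, 56.0))),
                initial_drop_fraction=float(d.get("initial_drop_fraction", 0.0)),
                noise_cv=float(d.get("noise_cv", 0.0)),
                seed=int(d.get("seed", 0)),
                batch=str(sample.get("id", "batch")),
                condition=str(sample.get("storage", "synthetic")),
            )
        )
    raise ValueError(f"sample {sample.get('id')} needs 'viability_csv' or a 'decay' spec")


def run_pipeline(config: str | Path | dict, output_dir: str | Path | None = None) -> dict:
    """Run segment -> thickness -> viability -> correlate end to end.

    Returns the summary dict (also written as ``summary.json``); artefacts:
    ``distributions/<sample>.csv``, ``halflives.csv``, ``association.csv``.
    Any stage failure aborts with the stage name and sample id.
    """
    cfg = _load_config(config)
    base_dir = Path(config).parent if not isinstance(config, dict) else Path.cwd()
    out_dir = Path(output_dir or cfg.get("output", {}).get("directory", "lyothick_out"))
    if not out_dir.is_absolute() and not isinstance(config, dict):
        out_dir = base_dir / out_dir
    (out_dir / "distributions").mkdir(parents=True, exist_ok=True)

    thick_cfg = cfg.get("thickness", {})
    bin_um = float(thick_cfg.get("bin_um", 0.5))
    weighting = thick_cfg.get("weighting", "voxel_volume")
    seg_cfg = cfg.get("segmentation", {})
    via_cfg = cfg.get("viability", {})
    windows = tuple(
        (float(a), float(b)) for a, b in via_cfg.get("windows", viab.DEFAULT_WINDOWS)
    )

    records: list[StudyRecord] = []
    estimates: list[viab.HalfLifeEstimate] = []
    sample_summaries = []
    for sample in cfg.get("samples", []):
        sid = str(sample.get("id", f"sample{len(records)}"))
        try:
            mask, log = _sample_mask(sample, seg_cfg)
            tmap = thick.local_thickness_map(mask, count_blobs=(weighting == "blob_volume"))
            dist = thick.thickness_distribution(tmap, bin_width_um=bin_um, weighting=weighting)
        except Exception as exc:  # noqa: BLE001 - annotate stage and sample
            raise RuntimeError(f"stage 'thickness' failed for sample {sid!r}: {exc}") from exc
        try:
            series = _sample_series(sample, base_dir)
            ests = viab.windowed_half_lives(series, windows=windows)
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"stage 'viability' failed for sample {sid!r}: {exc}") from exc

        thick.distribution_to_frame(dist).to_csv(
            out_dir / "distributions" / f"{sid}.csv", index=False
        )
        sub_res = thick.is_sub_resolution(dist)
        mode = SUB_RESOLUTION if sub_res else thick.distribution_mode(dist)
        d_vol = SUB_RESOLUTION if sub_res else thick.volume_weighted_mean(dist)
        t_half = {f"{int(e.t_start)}-{int(e.t_end)}d": e.t_half_days for e in ests}
        records.append(
            StudyRecord(
                sample_id=sid,
                thickness_mode_um=mode,
                d_vol_um=d_vol,
                t_half_days=t_half,
                annealing_protocol=str(sample.get("annealing", "")),
                storage=str(sample.get("storage", "")),
            )
        )
        estimates.extend(ests)
        sample_summaries.append(
            {
                "sample_id": sid,
                "mode_um": mode,
                "d_vol_um": d_vol,
                "sub_resolution": bool(sub_res),
                "material_fraction": mask.material_fraction,
                "t_half_days": t_half,
                **log,
            }
        )

    try:
        associations = correlate_thickness_stability(
            records, group_by=cfg.get("association", {}).get("group_by", "storage")
        )
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"stage 'correlate' failed: {exc}") from exc

    viab.half_lives_to_frame(estimates).to_csv(out_dir / "halflives.csv", index=False)
    assoc_df = pd.DataFrame(
        {
            "grouping": [a.grouping for a in associations],
            "window": [a.window for a in associations],
            "n": [a.n for a in associations],
            "pearson_r": [a.pearson_r for a in associations],
            "spearman_rho": [a.spearman_rho for a in associations],
            "slope_days_per_um": [a.slope_days_per_um for a in associations],
            "intercept_days": [a.intercept_days for a in associations],
            "n_excluded_sub_resolution": [a.n_excluded_sub_resolution for a in associations],
            "flags": [";".join(a.flags) for a in associations],
        }
    )
    assoc_df.to_csv(out_dir / "association.csv", index=False)

    summary = {
        "settings": {
            "bin_um": bin_um,
            "weighting": weighting,
            "segmentation": seg_cfg,
            "windows": [list(w) for w in windows],
        },
        "samples": sample_summaries,
        "association": assoc_df.to_dict(orient="records"),
    }
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
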