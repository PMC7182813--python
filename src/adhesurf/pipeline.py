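"""Programmatic pipeline stages wiring the analysis modules to files.

Each ``run_*`` function is a thin, deterministic wrapper: read the CSV/image
inputs in the package's interchange dialects, call the library, write CSV
outputs (full-precision plus display-rounded columns) and a JSON run
manifest recording the package version, a config hash, seeds and input
checksums.  Identical config and inputs give byte-identical outputs.

CSV dialects
------------
contact angles   surface,liquid,theta_mean,theta_sd,n_readings
liquid table     name,gamma_total,gamma_lw,gamma_ab,gamma_plus,gamma_minus
image manifest   image_path,condition_id
assay records    material,strain,pH,ionic_strength,treatment,mean_coverage,
                 sd_coverage,n_images
kinetic trace    '# key=value' metadata header lines (epsilon,path_length_cm,
                 volume_L,debris_mass_g) then time_s,absorbance
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

from . import coverage as cov
from . import energetics as en
from .assay import AdhesionRecord, assemble_table, records_from_frame, records_to_frame
from .enzymology import KineticTrace, measure_activity
from .liquids import TestLiquid, default_liquids, load_liquids
from .synthetic import (
    DEFAULT_BETWEEN_IMAGE_SD,
    MicrographSpec,
    gen_replicate_micrographs,
)

__all__ = [
    "RunConfig",
    "round_display",
    "run_energy",
    "run_coverage",
    "run_assay",
    "run_lipase",
    "run_simulate",
    "read_trace_csv",
    "write_trace_csv",
]

_VERSION = "0.1.0"


def round_display(x: float, ndigits: int = 1) -> float:
    """Half-up decimal rounding for display columns (as printed tables do)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class RunConfig:
    """Parameters of one pipeline stage run."""

    out_dir: Path
    seed: int = 0
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        self.out_dir.mkdir(parents=True, exist_ok=True)


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _write_manifest(config: RunConfig, stage: str, inputs: list[Path], outputs: list[Path]) -> Path:
    cfg_repr = json.dumps(
        {"stage": stage, "seed": config.seed, "params": config.params},
        sort_keys=True, default=str,
    )
    manifest = {
        "tool": "adhesurf",
        "version": _VERSION,
        "stage": stage,
        "seed": config.seed,
        "config_hash": hashlib.sha256(cfg_repr.encode()).hexdigest(),
        "inputs": {str(p): _sha256(p) for p in inputs},
        "outputs": [str(p) for p in outputs],
    }
    path = config.out_dir / f"{stage}_manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def run_energy(
    angles_csv: Path, config: RunConfig, liquids_csv: Path | None = None
) -> pd.DataFrame:
    """Angles CSV -> per-surface energy components CSV.

    Emits full-precision columns, one-decimal display columns, the
    negative-root flags, the Rijnaarts class from the water angle, and the
    per-liquid apolar-gamma^LW diagnostic.
    """
    angles_csv = Path(angles_csv)
    liquids = load_liquids(liquids_csv) if liquids_csv else default_liquids()
    by_name = {liq.name: liq for liq in liquids}
    df = pd.read_csv(angles_csv)
    rows = []
    for surface, grp in df.groupby("surface", sort=True):
        angles = [
            en.ContactAngleMeasurement(
                by_name[r["liquid"]],
                float(r["theta_mean"]),
                float(r.get("theta_sd", 0.0) or 0.0),
                int(r.get("n_readings", 10) or 10),
            )
            for _, r in grp.iterrows()
        ]
        comp = en.solve_components(angles, surface_name=str(surface))
        water = next(
            (a.theta_mean for a in angles if a.liquid.name == "water"), None
        )
        diag = en.apolar_lw_diagnostic(angles)
        rows.append(
            {
                "surface": surface,
                "gamma_lw": comp.gamma_lw,
                "gamma_plus": comp.gamma_plus,
                "gamma_minus": comp.gamma_minus,
                "gamma_ab": comp.gamma_ab,
                "gamma_total": comp.gamma_total,
                "gamma_lw_display": round_display(comp.gamma_lw),
                "gamma_plus_display": round_display(comp.gamma_plus),
                "gamma_minus_display": round_display(comp.gamma_minus),
                "gamma_ab_display": round_display(comp.gamma_ab),
                # printed tables sum rounded components; mirror that
                "gamma_total_display": round_display(
                    round_display(comp.gamma_lw) + round_display(comp.gamma_ab)
                ),
                "negative_root_flags": "".join(
                    "1" if f else "0" for f in comp.negative_root_flags
                ),
                "hydrophobicity_class": (
                    en.classify_hydrophobicity(water).value if water is not None else ""
                ),
                "apolar_lw_diagnostic": json.dumps(
                    {k: round(v, 3) for k, v in diag.items()}, sort_keys=True
                ),
            }
        )
    out = pd.DataFrame(rows)
    out_path = config.out_dir / "surface_energies.csv"
    out.to_csv(out_path, index=False)
    _write_manifest(config, "energy", [angles_csv], [out_path])
    return out


def _read_gray(path: Path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        return np.asarray(tifffile.imread(path))
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:  # collapse an RGB(A) read of a gray PNG
        arr = arr[..., :3].mean(axis=-1)
    return arr


def run_coverage(manifest_csv: Path, config: RunConfig) -> pd.DataFrame:
    """Image manifest -> per-image and per-condition coverage CSVs."""
    manifest_csv = Path(manifest_csv)
    mdf = pd.read_csv(manifest_csv)
    if mdf.empty:
        raise ValueError(f"empty image manifest: {manifest_csv}")
    p = config.params
    per_image, errors = [], []
    results_by_cond: dict[str, list[cov.CoverageResult]] = {}
    for _, row in mdf.iterrows():
        path = Path(row["image_path"])
        try:
            img = cov.Micrograph(
                _read_gray(path),
                image_id=path.stem,
                condition_id=str(row["condition_id"]),
            )
            res, mask = cov.analyze_micrograph(
                img,
                method=p.get("method", "otsu"),
                polarity=p.get("polarity", "dark_cells"),
                threshold=p.get("threshold"),
                min_object_px=p.get("min_object_px", cov.DEFAULT_MIN_OBJECT_PX),
                opening_radius=p.get("opening_radius", cov.DEFAULT_OPENING_RADIUS),
            )
        except (ValueError, OSError) as exc:
            errors.append(f"{path}: {exc}")
            continue
        per_image.append(
            {
                "image_id": res.image_id,
                "condition_id": res.condition_id,
                "coverage_fraction": res.coverage_fraction,
                "object_count": res.object_count,
                "threshold_used": mask.threshold_used,
            }
        )
        results_by_cond.setdefault(res.condition_id, []).append(res)
    if errors:
        raise RuntimeError(
            "coverage stage failed on %d input(s):\n%s" % (len(errors), "\n".join(errors))
        )
    img_df = pd.DataFrame(per_image)
    cond_df = pd.DataFrame(
        [
            {
                "condition_id": cid,
                "mean_coverage": s.mean_coverage,
                "sd_coverage": s.sd_coverage,
                "n_images": s.n_images,
            }
            for cid, s in (
                (cid, cov.summarize_replicates(res)) for cid, res in sorted(results_by_cond.items())
            )
        ]
    )
    p1 = config.out_dir / "coverage_per_image.csv"
    p2 = config.out_dir / "coverage_per_condition.csv"
    img_df.to_csv(p1, index=False)
    cond_df.to_csv(p2, index=False)
    _write_manifest(config, "coverage", [manifest_csv], [p1, p2])
    return cond_df


def run_assay(records_csv: Path, config: RunConfig) -> pd.DataFrame:
    """Records CSV -> wide condition table + lossless long CSV."""
    records_csv = Path(records_csv)
    records = records_from_frame(pd.read_csv(records_csv))
    rows = config.params.get("rows", "pH")
    columns = config.params.get("columns", ["material", "strain"])
    table = assemble_table(records, rows=rows, columns=columns)
    wide = config.out_dir / "assay_table_wide.csv"
    longp = config.out_dir / "assay_table_long.csv"
    table.to_csv(wide)
    records_to_frame(records).to_csv(longp, index=False)
    _write_manifest(config, "assay", [records_csv], [wide, longp])
    return table


def write_trace_csv(path: Path, trace: KineticTrace, epsilon: float) -> None:
    path = Path(path)
    header = (
        f"# epsilon={epsilon}\n"
        f"# path_length_cm={trace.path_length}\n"
        f"# volume_L={trace.reaction_volume}\n"
        f"# debris_mass_g={trace.debris_mass}\n"
    )
    body = pd.DataFrame({"time_s": trace.times, "absorbance": trace.absorbance})
    path.write_text(header + body.to_csv(index=False))


def read_trace_csv(path: Path) -> tuple[KineticTrace, float]:
    """Read a trace CSV; returns (trace, epsilon)."""
    path = Path(path)
    meta = {}
    with open(path) as fh:
        lines = fh.readlines()
    for line in lines:
        if line.startswith("#"):
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = float(val)
    df = pd.read_csv(path, comment="#")
    required = {"epsilon", "path_length_cm", "volume_L", "debris_mass_g"}
    missing = required - meta.keys()
    if missing:
        raise ValueError(f"{path}: missing trace metadata {sorted(missing)}")
    return (
        KineticTrace(
            times=df["time_s"].to_numpy(),
            absorbance=df["absorbance"].to_numpy(),
            reaction_volume=meta["volume_L"],
            debris_mass=meta["debris_mass_g"],
            path_length=meta["path_length_cm"],
        ),
        meta["epsilon"],
    )


def run_lipase(trace_csvs: list[Path], config: RunConfig) -> pd.DataFrame:
    """Trace CSVs -> specific-activity table (one row per sample)."""
    if not trace_csvs:
        raise ValueError("no trace files supplied")
    rows = []
    for path in trace_csvs:
        trace, epsilon = read_trace_csv(path)
        result = measure_activity(trace, epsilon=epsilon)
        rows.append(
            {
                "sample": Path(path).stem,
                "initial_rate_abs_per_s": result.initial_rate_abs_per_s,
                "activity_umol_per_min": result.activity_umol_per_min,
                "specific_activity_U_per_g": result.specific_activity,
                "specific_activity_display": round_display(result.specific_activity, 2),
                "r_squared": result.r_squared,
            }
        )
    out = pd.DataFrame(rows)
    out_path = config.out_dir / "lipase_activity.csv"
    out.to_csv(out_path, index=False)
    _write_manifest(config, "lipase", [Path(p) for p in trace_csvs], [out_path])
    return out


def run_simulate(config: RunConfig) -> pd.DataFrame:
    """Generate micrograph fixtures + manifest CSV in the coverage dialect.

    params: conditions — mapping condition_id -> true coverage;
    n_images per condition; any MicrographSpec overrides.
    """
    p = config.params
    conditions: dict[str, float] = p.get("conditions", {"demo": 0.3})
    n_images: int = p.get("n_images", 5)
    between_sd: float = p.get("between_image_sd", DEFAULT_BETWEEN_IMAGE_SD)
    spec_overrides = {
        k: v
        for k, v in p.items()
        if k in MicrographSpec.__dataclass_fields__ and k not in ("seed", "true_coverage")
    }
    import tifffile

    rows = []
    outputs = []
    rng = np.random.default_rng(config.seed)
    for cid, cov_true in sorted(conditions.items()):
        replicates = gen_replicate_micrographs(
            cov_true,
            n_images,
            between_image_sd=between_sd,
            seed=int(rng.integers(0, 2**31 - 1)),
            condition_id=cid,
            **spec_overrides,
        )
        for img, _, realized in replicates:
            path = config.out_dir / f"{img.image_id}.tif"
            tifffile.imwrite(path, img.pixels)
            outputs.append(path)
            rows.append(
                {
                    "image_path": str(path),
                    "condition_id": cid,
                    "condition_coverage": cov_true,
                    "realized_coverage": realized,
                }
            )
    mpath = config.out_dir / "image_manifest.csv"
    mdf = pd.DataFrame(rows)
    mdf.to_csv(mpath, index=False)
    _write_manifest(config, "simulate", [], outputs + [mpath])
    return mdf
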