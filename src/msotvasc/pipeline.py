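"""End-to-end synthetic-cohort run: phantom -> unmix -> segment -> volume ->
occlusion dynamics -> cohort tables.

Generates a seeded cohort of per-finger phantom cubes (healthy controls and
patients, the latter with baseline sO2 shifted down), analyses every cube
with the same operations a real acquisition would pass through, summarises
occlusion challenges for a participant subset, and writes the three
comparison tables (vascular volume, baseline sO2, occlusion metrics) plus
per-finger and per-subject CSVs and a run manifest. Identical seed =>
bit-identical table outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import (
    SubjectRecord,
    build_comparison_table,
    comparisons_to_frame,
    format_comparison_table,
)
from .dynamics import occlusion_metrics
from .io import PipelineConfig, RunManifest, sha256_of
from .phantom import (
    PhantomSpec,
    VesselSpec,
    make_finger_phantom,
    make_occlusion_series,
)
from .structure import (
    IntensityHistogram,
    apply_threshold,
    mean_over_fingers,
    moment_preserving_threshold,
    vascular_volume,
)
from .unmixing import (
    LN10,
    build_design_matrix,
    compute_so2,
    load_default_extinction_table,
    mean_so2,
    noise_floor_mask,
    unmix_pseudo_inverse,
)

__all__ = ["CohortRunResult", "run_demo_cohort", "analyse_finger_cube"]

N_FINGERS = 8
STRUCTURAL_WAVELENGTH_NM = 800.0


@dataclass
class CohortRunResult:
    """Everything produced by one demo-cohort run."""

    records: list[SubjectRecord]
    per_finger: pd.DataFrame
    subjects: pd.DataFrame
    tables: dict[str, pd.DataFrame]
    table_rows: dict[str, list] = field(default_factory=dict)
    output_dir: Path | None = None
    written: dict[str, Path] = field(default_factory=dict)


def analyse_finger_cube(cube, noise_floor: float, table=None):
    """Single-cube analysis: unmixing, sO2 averaging and volumetry.

    Returns ``(mean_so2, volume_result, threshold)``. The structural volume
    is segmented on the 800 nm plane with the moment-preserving threshold;
    oxygenation is averaged over voxels above the noise floor.
    """
    if table is None:
        table = load_default_extinction_table()
    design = build_design_matrix(table, cube.wavelengths)
    maps = unmix_pseudo_inverse(cube, design)
    valid = noise_floor_mask(maps, noise_floor)
    omap = compute_so2(maps, valid)
    so2 = mean_so2(omap)

    structural = cube.volume_at(STRUCTURAL_WAVELENGTH_NM)
    hist = IntensityHistogram.from_volume(structural)
    threshold = moment_preserving_threshold(hist)
    mask = apply_threshold(structural, threshold, cube.geometry)
    vol = vascular_volume(mask)
    return so2, vol, threshold


def _simulate_subject_fingers(config: PipelineConfig, subject_so2, rng):
    """One subject's 8 finger cubes analysed to per-finger measurements."""
    geom = config.geometry
    ext_x, ext_y, ext_z = geom.extent_mm
    table = load_default_extinction_table()
    design = table.interpolate(config.wavelengths_nm)
    # peak in-vessel signal for unit total haemoglobin, used to set noise
    peak_signal = LN10 * float(design.max())
    noise_sigma = config.noise_fraction_of_peak * peak_signal
    # the floor acts on unmixed total haemoglobin (concentration scale):
    # halfway between background (0) and the in-vessel total of 1.0
    noise_floor = 0.5

    rows = []
    for finger in range(N_FINGERS):
        finger_so2 = float(
            np.clip(
                subject_so2 + rng.normal(0.0, config.so2_between_finger_sd),
                0.05,
                0.95,
            )
        )
        radius = float(rng.uniform(0.18, 0.28))  # mm
        y_pos = float(rng.uniform(0.35, 0.65) * ext_y)
        z_pos = float(rng.uniform(0.35, 0.65) * ext_z)
        vessel = VesselSpec(
            axis_start=(0.0, y_pos, z_pos),
            axis_end=(ext_x, y_pos, z_pos),
            radius_mm=radius,
            hb=1.0 - finger_so2,
            hbo2=finger_so2,
        )
        spec = PhantomSpec(
            geometry=geom,
            vessels=(vessel,),
            wavelengths=config.wavelengths_nm,
            noise_sigma=noise_sigma,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        cube, truth = make_finger_phantom(spec, table=table)
        so2, vol, threshold = analyse_finger_cube(cube, noise_floor, table)
        rows.append(
            {
                "finger": finger + 1,
                "true_so2": finger_so2,
                "true_volume_mm3": truth.total_vessel_volume_mm3,
                "baseline_so2": so2,
                "n_voxels": vol.n_voxels,
                "voxel_volume_mm3": vol.voxel_volume_mm3,
                "total_volume_mm3": vol.total_volume_mm3,
                "threshold": threshold,
            }
        )
    return rows


def _simulate_occlusion(config: PipelineConfig, subject_so2, is_ssc, rng):
    """One subject's occlusion challenge, summarised to three metrics."""
    baseline = float(np.clip(subject_so2 + rng.normal(0.0, 0.002), 0.05, 0.95))
    trough = max(baseline - float(rng.uniform(0.012, 0.022)), 0.0)
    overshoot = 0.003 if is_ssc else 0.005
    peak = min(baseline + overshoot + float(rng.normal(0.0, 0.001)), 1.0)
    series = make_occlusion_series(
        baseline_so2=baseline,
        trough_so2=trough,
        peak_so2=max(peak, trough),
        events=config.events,
        sample_interval_s=config.occlusion_sample_interval_s,
        noise_sigma=config.occlusion_noise_sigma,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    m = occlusion_metrics(series, config.events)
    return {
        "occ_baseline_so2": m.baseline_so2,
        "occ_min_so2": m.min_so2,
        "occ_max_so2": m.max_so2,
    }


def run_demo_cohort(
    config: PipelineConfig, output_dir: str | Path | None = None
) -> CohortRunResult:
    """Simulate and analyse a full cohort; optionally write all outputs."""
    rng = np.random.default_rng(config.seed)
    records: list[SubjectRecord] = []
    per_finger_rows = []

    roster = [("HC", i) for i in range(config.n_hc)] + [
        ("SSc", i) for i in range(config.n_ssc)
    ]
    for group, i in roster:
        is_ssc = group == "SSc"
        subgroup = "none"
        if is_ssc:
            subgroup = "SSc_isch" if i < config.n_ssc_isch else "SSc_no_isch"
        subject_id = f"{group}{i + 1:03d}"
        mean = config.ssc_so2_mean if is_ssc else config.hc_so2_mean
        subject_so2 = float(
            np.clip(
                mean + rng.normal(0.0, config.so2_between_subject_sd),
                0.05,
                0.95,
            )
        )
        finger_rows = _simulate_subject_fingers(config, subject_so2, rng)
        for row in finger_rows:
            per_finger_rows.append(
                {"subject_id": subject_id, "group": group, **row}
            )
        record = SubjectRecord(
            subject_id=subject_id,
            group=group,
            subgroup=subgroup,
            fingers={
                "baseline_so2": [r["baseline_so2"] for r in finger_rows],
                "vascular_volume_mm3": [
                    r["total_volume_mm3"] for r in finger_rows
                ],
            },
        )
        n_occ = config.n_occlusion_ssc if is_ssc else config.n_occlusion_hc
        if i < n_occ:
            record.occlusion = _simulate_occlusion(
                config, subject_so2, is_ssc, rng
            )
        records.append(record)

    per_finger = pd.DataFrame(per_finger_rows)
    subjects = pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "group": [r.group for r in records],
            "subgroup": [r.subgroup for r in records],
            "mean_volume_mm3": [
                mean_over_fingers(r.fingers["vascular_volume_mm3"])
                for r in records
            ],
            "mean_baseline_so2": [
                mean_over_fingers(r.fingers["baseline_so2"]) for r in records
            ],
        }
    )

    mode = config.mwu_mode
    table_rows = {
        "table2_vascular_volume": build_comparison_table(
            records, "vascular_volume_mm3", level="mean8", mode=mode
        ),
        "table3_baseline_so2": build_comparison_table(
            records, "baseline_so2", level="mean8", mode=mode
        ),
        "table4_occlusion": [
            row
            for metric in ("occ_baseline_so2", "occ_min_so2", "occ_max_so2")
            for row in build_comparison_table(
                records, metric, level="mean8", mode=mode
            )
        ],
    }
    tables = {
        name: comparisons_to_frame(rows) for name, rows in table_rows.items()
    }

    result = CohortRunResult(
        records=records,
        per_finger=per_finger,
        subjects=subjects,
        tables=tables,
        table_rows=table_rows,
    )
    if output_dir is not None:
        result.output_dir = Path(output_dir)
        _write_outputs(config, result)
    return result


def _write_outputs(config: PipelineConfig, result: CohortRunResult) -> None:
    out = result.output_dir
    assert out is not None
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config={}, software_version=__version__, started_utc=RunManifest.now()
    )
    written: dict[str, Path] = {}

    written["config"] = config.to_yaml(out / "config.yaml")
    result.per_finger.to_csv(out / "per_finger.csv", index=False)
    written["per_finger"] = out / "per_finger.csv"
    result.subjects.to_csv(out / "subjects.csv", index=False)
    written["subjects"] = out / "subjects.csv"
    for name, frame in result.tables.items():
        csv_path = out / f"{name}.csv"
        frame.to_csv(csv_path, index=False)
        written[name] = csv_path
        decimals = 1 if "volume" in name else 3
        txt = format_comparison_table(
            result.table_rows[name], decimals=decimals
        )
        (out / f"{name}.txt").write_text(txt + "\n")
        written[f"{name}_txt"] = out / f"{name}.txt"

    import yaml as _yaml

    manifest.config = _yaml.safe_load((out / "config.yaml").read_text())
    manifest.output_checksums = {
        name: sha256_of(path) for name, path in sorted(written.items())
    }
    manifest.finished_utc = RunManifest.now()
    manifest.write(out / "manifest.json")
    written["manifest"] = out / "manifest.json"
    result.written = written
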