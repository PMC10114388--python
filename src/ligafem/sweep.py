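"""Study orchestration: elastin-content sweep and sheet-vs-fibre comparison.

`run_sweep` builds a fibre model per requested content, runs the three load
protocols, summarizes collagen stress/displacement, fits stress-strain
slopes, appends a sheet-model row, and emits the study tables (rotation
stresses per content; per-case collagen statistics; model-comparison
ratios).  Everything is deterministic: identical configs yield identical
CSV bytes.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ComparisonError, LigafemError
from .geometry import (
    Material,
    TABLE_MATERIALS,
    build_fibre_model,
    build_sheet_model,
    elastin_fraction,
    n_for_content,
)
from .io import write_vtu
from .loads import LoadCase, LoadRunner
from .mesh import voxelize
from .metrics import stress_strain_slope, summarize

__all__ = ["StudyConfig", "SweepTable", "run_sweep", "compare_models"]

log = logging.getLogger("ligafem.sweep")

#: the ten sweep contents of the study, in percent
DEFAULT_CONTENTS_PCT = (0.0, 5.3, 10.1, 14.4, 18.3, 21.8, 25.1, 28.1, 30.9, 33.5)


@dataclass
class StudyConfig:
    """Full parametric description of the study (lengths in um)."""

    rows: int = 3
    cols: int = 5
    fibre_dims_um: tuple = (300.0, 20.0, 20.0)
    elastin_dims_um: tuple = (20.0, 12.0, 12.0)
    gap_um: float = 20.0
    bone_thickness_um: float = 40.0
    sheet_dims_um: tuple = (300.0, 62.0, 128.0)
    voxel_um: float = 4.0
    #: per-axis spacing for the sheet (its 62 um width is not divisible by 4)
    sheet_voxel_um: tuple = (4.0, 3.875, 4.0)
    contents_pct: tuple = DEFAULT_CONTENTS_PCT
    tensile_pa: float = 0.15
    shear_pa: float = 0.90e-3
    rotation_deg: float = 30.0
    slope_scalings: tuple = (1.0, 2.0)
    sheet_reference_content_pct: float = 14.4
    materials: dict[str, Material] = field(
        default_factory=lambda: dict(TABLE_MATERIALS)
    )

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["materials"] = {
            k: {"E_Pa": m.young_modulus, "nu": m.poisson_ratio}
            for k, m in self.materials.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        if "materials" in d:
            d["materials"] = {
                k: Material(k, v["E_Pa"], v["nu"]) for k, v in d["materials"].items()
            }
        for key in (
            "fibre_dims_um",
            "elastin_dims_um",
            "sheet_dims_um",
            "sheet_voxel_um",
            "contents_pct",
            "slope_scalings",
        ):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path) -> None:
        d = self.to_dict()
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    def cache_key(self, model: str, extra: str = "") -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(f"{payload}|{model}|{extra}".encode()).hexdigest()[:16]


@dataclass
class SweepTable:
    """Content-indexed study table plus completeness bookkeeping."""

    table: pd.DataFrame
    config: StudyConfig
    partial: bool = False
    failures: list = field(default_factory=list)

    def fibre_row(self, content_pct: float) -> pd.Series:
        fib = self.table[self.table["model"] == "fibre"]
        match = fib[np.isclose(fib["elastin_content_pct"], content_pct, atol=0.05)]
        if match.empty:
            raise ComparisonError(f"no fibre row at content {content_pct}%")
        return match.iloc[0]

    def sheet_row(self) -> pd.Series:
        sh = self.table[self.table["model"] == "sheet"]
        if sh.empty:
            raise ComparisonError("no sheet row in the sweep table")
        return sh.iloc[0]


def _model_row(cfg: StudyConfig, model: str, n: int | None, write_dir: Path | None):
    """Build, mesh, run the three protocols, and summarize one model."""
    if model == "fibre":
        g = build_fibre_model(
            rows=cfg.rows,
            cols=cfg.cols,
            fibre_dims=cfg.fibre_dims_um,
            elastin_dims=cfg.elastin_dims_um,
            gap=cfg.gap_um,
            n_elastin=n,
            bone_thickness=cfg.bone_thickness_um,
            materials=cfg.materials,
        )
        mesh = voxelize(g, cfg.voxel_um)
        ligament = "collagen"
        content_pct = 100.0 * elastin_fraction(g)
    else:
        g = build_sheet_model(
            dims=cfg.sheet_dims_um,
            bone_thickness=cfg.bone_thickness_um,
            materials=cfg.materials,
        )
        mesh = voxelize(g, cfg.sheet_voxel_um)
        ligament = "sheet"
        content_pct = float("nan")

    runner = LoadRunner(g, mesh)
    row: dict = {
        "model": model,
        "elastin_content_pct": content_pct,
        "n_elastin": n if n is not None else 0,
        "n_elements": mesh.n_elements,
    }
    results = {}
    for kind, mag in (
        ("tensile", cfg.tensile_pa),
        ("shear", cfg.shear_pa),
        ("rotation", cfg.rotation_deg),
    ):
        t0 = time.perf_counter()
        res = runner.run(LoadCase(kind, mag))
        log.info(
            "%s n=%s %s: solved %d DOF in %.1f s",
            model, n, kind, 3 * mesh.n_nodes, time.perf_counter() - t0,
        )
        results[kind] = res
        s = summarize(res, ligament)
        row[f"{kind}_mean_vm_Pa"] = s.mean_vm
        row[f"{kind}_max_vm_Pa"] = s.max_vm
        row[f"{kind}_mean_disp_m"] = s.mean_disp
        row[f"{kind}_max_disp_m"] = s.max_disp
        if kind == "rotation":
            row["sigma_y_MPa"] = res.sigma_y / 1e6
            row["sigma_z_MPa"] = res.sigma_z / 1e6
        else:
            row[f"{kind}_strain"] = res.global_strain
    for kind in ("tensile", "shear"):
        est = stress_strain_slope(
            g, mesh, kind, scalings=cfg.slope_scalings, runner=runner
        )
        row[f"slope_{kind}_Pa"] = est.slope
    if write_dir is not None:
        write_dir.mkdir(parents=True, exist_ok=True)
        tag = f"{model}" + (f"_n{n}" if model == "fibre" else "")
        for kind, res in results.items():
            write_vtu(
                mesh,
                write_dir / f"{tag}_{kind}.vtu",
                point_data={"displacement": res.displacement},
                cell_data={"von_mises": res.stress["von_mises"]},
            )
    return row


def run_sweep(
    config: StudyConfig | None = None,
    out_dir: str | Path | None = None,
    cache_dir: str | Path | None = None,
    write_fields: bool = False,
) -> SweepTable:
    """Run the full content sweep plus the sheet model.

    Per-model rows are cached (keyed by a hash of the config and model) when
    ``cache_dir`` is given.  A row that fails is logged and skipped; the
    returned table is then flagged partial.
    """
    cfg = config or StudyConfig()
    cache = Path(cache_dir) if cache_dir else None
    if cache:
        cache.mkdir(parents=True, exist_ok=True)
    vtu_dir = Path(out_dir) / "fields" if (out_dir and write_fields) else None

    jobs: list[tuple[str, int | None]] = []
    for pct in cfg.contents_pct:
        jobs.append(
            (
                "fibre",
                n_for_content(
                    pct / 100.0,
                    rows=cfg.rows,
                    cols=cfg.cols,
                    fibre_dims=cfg.fibre_dims_um,
                    elastin_dims=cfg.elastin_dims_um,
                    gap=cfg.gap_um,
                ),
            )
        )
    jobs.append(("sheet", None))

    rows, failures = [], []
    for model, n in jobs:
        key = cfg.cache_key(model, extra=str(n))
        cached = cache / f"{key}.json" if cache else None
        if cached and cached.exists():
            rows.append(json.loads(cached.read_text()))
            log.info("%s n=%s: cache hit (%s)", model, n, key)
            continue
        try:
            row = _model_row(cfg, model, n, vtu_dir)
        except LigafemError as err:
            log.error("%s n=%s failed: %s", model, n, err)
            failures.append({"model": model, "n_elastin": n, "error": str(err)})
            continue
        rows.append(row)
        if cached:
            cached.write_text(json.dumps(row))

    table = pd.DataFrame(rows)
    sweep = SweepTable(table, cfg, partial=bool(failures), failures=failures)
    if out_dir is not None:
        write_tables(sweep, out_dir)
    return sweep


def write_tables(sweep: SweepTable, out_dir: str | Path) -> None:
    """Write table2.csv, fig5.csv and fig3_ratios.csv under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t = sweep.table
    fib = t[t["model"] == "fibre"]

    table2 = t[["model", "elastin_content_pct", "sigma_y_MPa", "sigma_z_MPa"]]
    table2.to_csv(out / "table2.csv", index=False)

    fig5_cols = [
        "elastin_content_pct",
        "tensile_mean_vm_Pa",
        "tensile_mean_disp_m",
        "slope_tensile_Pa",
        "shear_mean_vm_Pa",
        "shear_mean_disp_m",
        "slope_shear_Pa",
    ]
    fib[fig5_cols].to_csv(out / "fig5.csv", index=False)

    try:
        ratios = compare_models(sweep, sweep.config.sheet_reference_content_pct)
        pd.DataFrame([ratios]).to_csv(out / "fig3_ratios.csv", index=False)
    except ComparisonError as err:
        log.warning("skipping fig3_ratios.csv: %s", err)
    if sweep.partial:
        (out / "FAILURES.json").write_text(json.dumps(sweep.failures, indent=2))


def compare_models(sweep: SweepTable, content_pct: float = 14.4) -> dict:
    """Sheet-vs-fibre ratio report at one elastin content.

    Rotation "stress required" ratios are sheet/fibre (the sheet is stiffer);
    per-case maximum-stress ratios are fibre/sheet (the fibre model
    concentrates stress).
    """
    fib = sweep.fibre_row(content_pct)
    sh = sweep.sheet_row()
    report = {
        "content_pct": float(fib["elastin_content_pct"]),
        "rotation_sigma_y_sheet_over_fibre": sh["sigma_y_MPa"] / fib["sigma_y_MPa"],
        "rotation_sigma_z_sheet_over_fibre": sh["sigma_z_MPa"] / fib["sigma_z_MPa"],
    }
    for kind in ("tensile", "shear", "rotation"):
        report[f"{kind}_max_vm_fibre_over_sheet"] = (
            fib[f"{kind}_max_vm_Pa"] / sh[f"{kind}_max_vm_Pa"]
        )
        report[f"{kind}_mean_vm_fibre_over_sheet"] = (
            fib[f"{kind}_mean_vm_Pa"] / sh[f"{kind}_mean_vm_Pa"]
        )
    return report
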