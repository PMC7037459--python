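"""End-to-end orchestration: activity fold changes and multi-stage reports.

``run_report`` chains the scan / ITC-fit / melt-fit stages over a bundle of
input files and writes one TSV per stage plus a JSON header that embeds the
full configuration (paths, thresholds, fit settings, seed, package
version) so every report is reproducible byte-for-byte from its own
provenance block.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

import capi
from capi.structure_io import read_pdb, StructureModel
from capi.geometry_core import RingSpec, Thresholds, bridge_scan, cation_pi_geometry, TRP_RING_6, TRP_RING_H
from capi.binding_thermo import ITCSchedule, Thermogram, fit_itc, kd_apparent
from capi.spectro_fits import MeltCurve, fit_melt


class IncompleteRowError(ValueError):
    """An activity table row is missing a required condition."""


@dataclass
class ActivityTable:
    """Guanylate-cyclase activity per variant and condition.

    Rows are (variant, condition, activity) with condition in
    {"EGTA", "high-Ca"} and activity in nmol cGMP / (min * mg protein).
    """

    rows: list[tuple[str, str, float]]

    def __post_init__(self) -> None:
        for variant, cond, act in self.rows:
            if cond not in ("EGTA", "high-Ca"):
                raise ValueError(f"unknown condition {cond!r} for {variant}")
            if act < 0:
                raise ValueError(f"negative activity for {variant}/{cond}")

    @classmethod
    def from_csv(cls, path: str | Path) -> "ActivityTable":
        df = pd.read_csv(path)
        return cls([(str(r.variant), str(r.condition), float(r.activity)) for r in df.itertuples()])

    def activity(self, variant: str, condition: str) -> float:
        for v, c, a in self.rows:
            if v == variant and c == condition:
                return a
        raise IncompleteRowError(f"no row for {variant}/{condition}")


def fold_changes(table: ActivityTable, reference_variant: str = "WT") -> pd.DataFrame:
    """Per-variant fold-change arithmetic on an activity table.

    Columns: ``max_activation_vs_ref`` (reference EGTA activity divided by
    the variant's — how many-fold lower the variant's maximal cGMP
    synthesis is) and ``inhibition_fold`` (EGTA over high-Ca activity — how
    strongly calcium shuts the cyclase down through this variant).
    Division-by-zero rows are flagged with NaN and ``flag="zero-division"``.
    """
    variants = sorted({v for v, _, _ in table.rows}, key=lambda v: (v != reference_variant, v))
    ref_egta = table.activity(reference_variant, "EGTA")
    out = []
    for variant in variants:
        egta = table.activity(variant, "EGTA")
        high = table.activity(variant, "high-Ca")
        flag = ""
        max_act = ref_egta / egta if egta > 0 else float("nan")
        inhib = egta / high if high > 0 else float("nan")
        if egta == 0 or high == 0:
            flag = "zero-division"
        out.append({
            "variant": variant,
            "activity_EGTA_nmol_cGMP_min_mg": egta,
            "activity_highCa_nmol_cGMP_min_mg": high,
            "max_activation_vs_ref": max_act,
            "inhibition_fold": inhib,
            "flag": flag,
        })
    return pd.DataFrame(out)


@dataclass
class RunConfig:
    """Everything a report run depends on; serialized into the report header."""

    output_dir: str
    bridge_pdb: str | None = None
    itc_csv: str | None = None
    melt_csv: str | None = None
    activity_csv: str | None = None
    cation_residues: tuple[tuple[str, int], ...] = (("A", 86),)
    ring_residues: tuple[tuple[str, int], ...] = (("A", 21), ("A", 94))
    thresholds: Thresholds = field(default_factory=Thresholds)
    itc_n_classes: int = 3
    itc_cell_uM: float = 20.0
    itc_syringe_mM: float = 0.5
    itc_injection_uL: float = 5.0
    n_starts: int = 32
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["thresholds"] = dataclasses.asdict(self.thresholds)
        return d

    def digest(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def scan_table(model: StructureModel, config: RunConfig, frame_index: int = 0) -> pd.DataFrame:
    """TSV-shaped cation-pi scan: one row per cation-ring pair plus bridges."""
    rows = []
    from capi.geometry_core import resolve_cation_point
    rings = [RingSpec(c, r, "", TRP_RING_6, TRP_RING_H) for c, r in config.ring_residues]
    for cat in config.cation_residues:
        cation_point = resolve_cation_point(model, cat[0], cat[1])
        for ring in rings:
            ring_atoms, hyds = ring.resolve(model)
            if len(ring_atoms) < 3:
                continue
            g = cation_pi_geometry(ring_atoms, cation_point, hyds,
                                   frame_index=frame_index, thresholds=config.thresholds)
            rows.append({
                "frame": frame_index,
                "cation": f"{cat[0]}:{cat[1]}",
                "ring": f"{ring.chain_id}:{ring.residue_number}",
                "theta_deg": round(g.theta, 3),
                "phi_deg": round(g.phi, 3) if not g.phi_missing else float("nan"),
                "d_A": round(g.distance, 4),
                "label": g.label,
            })
    bridges = bridge_scan(model, config.cation_residues, rings, config.thresholds,
                          frame_index=frame_index)
    for b in bridges:
        rows.append({
            "frame": frame_index,
            "cation": f"{b.cation[0]}:{b.cation[1]}",
            "ring": f"bridge:{b.ring_a.residue_number}+{b.ring_b.residue_number}",
            "theta_deg": float("nan"), "phi_deg": float("nan"), "d_A": float("nan"),
            "label": f"bridge[{b.geometry_a.label}/{b.geometry_b.label}]",
        })
    return pd.DataFrame(rows)


def _itc_fit_table(csv_path: str, config: RunConfig) -> pd.DataFrame:
    df = pd.read_csv(csv_path)
    heats = df["heat_ucal"].to_numpy(dtype=float)
    if "blank_heat_ucal" in df.columns:
        heats = heats - df["blank_heat_ucal"].to_numpy(dtype=float)
    inj = df["injection_volume_uL"].to_numpy(dtype=float) * 1e-6
    schedule = ITCSchedule(
        cell_concentration=config.itc_cell_uM * 1e-6,
        syringe_concentration=config.itc_syringe_mM * 1e-3,
        injection_volumes=tuple(inj),
    )
    fit = fit_itc(Thermogram(heats, schedule.concentrations()[0]), schedule,
                  n_classes=config.itc_n_classes, n_starts=config.n_starts, seed=config.seed)
    rows = []
    for i, ((kd, dh), kd_err, dh_err, bad) in enumerate(
            zip(fit.model.site_classes, fit.kd_stderr, fit.dh_stderr, fit.unidentifiable), start=1):
        unit, scale = ("uM", 1e6) if kd >= 1e-6 else ("nM", 1e9)
        rows.append({
            "site_class": i,
            f"KD": f"{kd * scale:.3g} {unit}",
            "KD_molar": kd,
            "KD_stderr_molar": kd_err,
            "dH_kcal_mol": dh,
            "dH_stderr_kcal_mol": dh_err,
            "unidentifiable": bool(bad),
        })
    table = pd.DataFrame(rows)
    table.attrs["kd_apparent_molar"] = fit.kd_apparent
    table.attrs["residual_sd_ucal"] = fit.residual_sd
    return table


def run_report(config: RunConfig) -> Path:
    """Run every stage with an input file and write TSV/JSON artifacts.

    Deterministic for a fixed config (the seed covers all randomness);
    rerunning with the same config yields byte-identical TSVs.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[dict] = []
    header = {
        "package": "capi",
        "version": capi.__version__,
        "config": config.to_dict(),
        "config_sha256_16": config.digest(),
    }

    def stage(name: str, fn, path: str | None):
        if path is None:
            return
        t0 = time.perf_counter()
        try:
            fn(path)
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed on {path}: {exc}") from exc
        log.append({"stage": name, "input": path,
                    "input_sha256_16": hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16],
                    "elapsed_s": round(time.perf_counter() - t0, 3)})

    def do_scan(path):
        obj = read_pdb(path)
        model = obj if isinstance(obj, StructureModel) else obj.model(0)
        scan_table(model, config).to_csv(out / "scan.tsv", sep="\t", index=False)

    def do_itc(path):
        table = _itc_fit_table(path, config)
        kdapp = table.attrs["kd_apparent_molar"]
        table.to_csv(out / "itc_fit.tsv", sep="\t", index=False)
        header["kd_apparent_molar"] = kdapp

    def do_melt(path):
        df = pd.read_csv(path)
        fit = fit_melt(MeltCurve(df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float)))
        pd.DataFrame([{
            "theta_folded_mdeg": fit.theta_folded,
            "theta_unfolded_mdeg": fit.theta_unfolded,
            "Tm_C": fit.tm_report,
            "hill_h": fit.h,
            "censored": fit.censored,
        }]).to_csv(out / "melt_fit.tsv", sep="\t", index=False)

    def do_fold(path):
        fold_changes(ActivityTable.from_csv(path)).to_csv(out / "fold.tsv", sep="\t", index=False)

    stage("scan", do_scan, config.bridge_pdb)
    stage("itc_fit", do_itc, config.itc_csv)
    stage("melt_fit", do_melt, config.melt_csv)
    stage("fold", do_fold, config.activity_csv)
    header["stages"] = log
    (out / "report.json").write_text(json.dumps(header, indent=2, sort_keys=True) + "\n")
    return out
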