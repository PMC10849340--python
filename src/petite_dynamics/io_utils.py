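"""File formats, input validation, and workflow orchestration.

Table dialects: UTF-8, mandatory header row, '.' decimal separator, NA for
missing.  Times are serialized in hours for model/assay tables and minutes
for plate-reader tables (instrument convention); everything is converted to
hours internally.  Model parameters load from TOML; run configurations from
YAML; reports are JSON.
"""

from __future__ import annotations

import json
import tomllib
import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError
from .growth import FitConfig, GrowthCurve, fit_exponential_rate
from .petite import estimate_loss_rate
from .screen import (
    BarcodeMaps,
    CountMatrix,
    ReadLayout,
    ScreenConfig,
    demultiplex_counts,
    run_contrast,
    select_hits,
)
from .two_state import PopulationTrajectory, TwoStateParams

__all__ = [
    "load_params_toml",
    "trajectory_to_tsv",
    "read_plate_csv",
    "read_group_map",
    "write_fits_tsv",
    "read_colony_csv",
    "read_series_tsv",
    "write_series_tsv",
    "read_gene_barcode_tsv",
    "read_index_tsv",
    "write_counts_tsv",
    "read_counts_tsv",
    "write_fastq",
    "validate_inputs",
    "run_workflow",
]


# ---------------------------------------------------------------- model I/O

def load_params_toml(path) -> TwoStateParams:
    """Two-state model parameters from a TOML file with keys g_wt, g_mut,
    r and optional p_wt0, p_mut0 (top level or under [model])."""
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    block = data.get("model", data)
    try:
        return TwoStateParams(
            g_wt=float(block["g_wt"]),
            g_mut=float(block["g_mut"]),
            r=float(block["r"]),
            p_wt0=float(block.get("p_wt0", 1.0)),
            p_mut0=float(block.get("p_mut0", 0.0)),
        )
    except KeyError as exc:
        raise ValidationError(f"missing model parameter {exc}") from exc


def trajectory_to_tsv(traj: PopulationTrajectory, path) -> None:
    df = pd.DataFrame(
        {"time_h": traj.times, "p_wt": traj.p_wt, "p_mut": traj.p_mut, "f": traj.f}
    )
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------- growth I/O

def read_plate_csv(path) -> list[GrowthCurve]:
    """Plate-reader CSV: column ``time_min`` then one OD column per well."""
    df = pd.read_csv(path)
    if "time_min" not in df.columns:
        raise ValidationError("plate CSV must have a 'time_min' column")
    t = df["time_min"].to_numpy(dtype=float)
    return [
        GrowthCurve(curve_id=col, times_min=t, od600=df[col].to_numpy(dtype=float))
        for col in df.columns
        if col != "time_min"
    ]


def read_group_map(path) -> pd.DataFrame:
    """Well-to-group TSV with columns well, strain, condition, replicate."""
    df = pd.read_csv(path, sep="\t")
    if "well" not in df.columns:
        raise ValidationError("group map must have a 'well' column")
    return df


def write_fits_tsv(fits, path) -> None:
    rows = [
        {
            "curve_id": f.curve_id,
            "rate_per_h": f.rate,
            "intercept_ln_od": f.intercept,
            "window_start": f.window[0],
            "window_stop": f.window[1],
            "r_squared": f.r_squared,
            "n_points": f.n_points,
        }
        for f in fits
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------- petite I/O

def read_colony_csv(path) -> pd.DataFrame:
    """Colony CSV: plate_id, colony_id, area_mm2, respiring (true/false/NA)."""
    df = pd.read_csv(path)
    req = {"plate_id", "colony_id", "area_mm2"}
    if req - set(df.columns):
        raise ValidationError(f"colony CSV missing {sorted(req - set(df.columns))}")
    if "respiring" in df.columns:
        df["respiring"] = df["respiring"].map(
            {True: True, False: False, "true": True, "false": False,
             "True": True, "False": False}
        )
    return df


def read_series_tsv(path) -> pd.DataFrame:
    """Petite time-series TSV: replicate, genotype, time_h, n_total, n_petite."""
    df = pd.read_csv(path, sep="\t")
    req = {"replicate", "genotype", "time_h", "n_total", "n_petite"}
    if req - set(df.columns):
        raise ValidationError(f"series TSV missing {sorted(req - set(df.columns))}")
    return df


def write_series_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------- screen I/O

def read_gene_barcode_tsv(path) -> dict:
    df = pd.read_csv(path, sep="\t")
    if {"gene_id", "barcode"} - set(df.columns):
        raise ValidationError("gene barcode TSV needs columns gene_id, barcode")
    return dict(zip(df["gene_id"], df["barcode"]))


def read_index_tsv(path) -> pd.DataFrame:
    """Sample sheet TSV: sample_id, index, condition, replicate."""
    df = pd.read_csv(path, sep="\t")
    req = {"sample_id", "index", "condition", "replicate"}
    if req - set(df.columns):
        raise ValidationError(f"index TSV missing {sorted(req - set(df.columns))}")
    return df


def write_counts_tsv(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_counts_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def write_fastq(reads: Sequence[tuple[str, str]], path, quality_char: str = "I") -> None:
    """Write (id, sequence) pairs as 4-line FASTQ records with constant
    Phred+33 quality."""
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{quality_char * len(seq)}\n")


# ------------------------------------------------------------- validation

def _check_fastq(path, issues: list) -> None:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) % 4 != 0:
        issues.append(f"{path}: FASTQ record count not a multiple of 4")
        return
    for i in range(0, len(lines), 4):
        if not lines[i].startswith("@"):
            issues.append(f"{path}: record {i // 4 + 1} header missing '@'")
            break
        if not lines[i + 2].startswith("+"):
            issues.append(f"{path}: record {i // 4 + 1} separator missing '+'")
            break
        if len(lines[i + 1]) != len(lines[i + 3]):
            issues.append(
                f"{path}: record {i // 4 + 1} sequence/quality length mismatch"
            )
            break


def validate_inputs(paths: Mapping[str, str]) -> list[str]:
    """Schema-check input files; returns a list of issues (empty = valid).

    ``paths`` maps kind -> path, with kinds among: plate_csv, group_tsv,
    colony_csv, series_tsv, gene_barcode_tsv, index_tsv, counts_tsv, fastq.
    Issues are collected, not raised one at a time.
    """
    issues: list[str] = []
    for kind, path in paths.items():
        p = Path(path)
        if not p.exists():
            issues.append(f"{path}: file not found")
            continue
        try:
            if kind == "plate_csv":
                curves = read_plate_csv(p)
                if not curves:
                    issues.append(f"{path}: no well columns")
            elif kind == "group_tsv":
                read_group_map(p)
            elif kind == "colony_csv":
                df = read_colony_csv(p)
                if (df["area_mm2"] <= 0).any():
                    issues.append(f"{path}: colony areas must be > 0")
            elif kind == "series_tsv":
                df = read_series_tsv(p)
                if (df["n_total"] <= 0).any():
                    issues.append(f"{path}: n_total must be > 0")
                if ((df["n_petite"] < 0) | (df["n_petite"] > df["n_total"])).any():
                    issues.append(f"{path}: need 0 <= n_petite <= n_total")
            elif kind == "gene_barcode_tsv":
                read_gene_barcode_tsv(p)
            elif kind == "index_tsv":
                read_index_tsv(p)
            elif kind == "counts_tsv":
                df = read_counts_tsv(p)
                if (df.values < 0).any():
                    issues.append(f"{path}: counts must be >= 0")
            elif kind == "fastq":
                _check_fastq(p, issues)
            else:
                issues.append(f"{path}: unknown input kind {kind!r}")
        except (ValidationError, ValueError, KeyError) as exc:
            issues.append(f"{path}: {exc}")
    return issues


# ------------------------------------------------------------- workflows

def _sub_seeds(seed: int, n: int) -> list[int]:
    """Logged, reproducible per-stage seeds derived from the global seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def load_run_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "workflow" not in cfg:
        raise ValidationError("run config must be a mapping with a 'workflow' key")
    return cfg


def run_workflow(config: dict, out_dir, seed: int | None = None) -> dict:
    """Execute a named workflow and write its artifacts under ``out_dir``.

    Workflows: ``simulate`` (write a full synthetic input set),
    ``loss_rate`` (petite series -> loss-rate report), ``screen`` (FASTQ or
    counts -> enrichment results and hit lists).  Returns the JSON report
    (also written to ``out_dir/report.json``).  Identical config and seed
    reproduce identical outputs.
    """
    from . import synthetic

    workflow = config.get("workflow")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0) if seed is None else seed)
    report: dict = {"workflow": workflow, "seed": seed, "outputs": {}}

    if workflow == "simulate":
        s_series, s_plate, s_colony, s_reads, s_counts = _sub_seeds(seed, 5)
        report["sub_seeds"] = {
            "series": s_series, "plate": s_plate, "colonies": s_colony,
            "reads": s_reads, "counts": s_counts,
        }
        mcfg = config.get("model", {})
        params = TwoStateParams(
            g_wt=mcfg.get("g_wt", 0.4),
            g_mut=mcfg.get("g_mut", 0.4),
            r=mcfg.get("r", 0.15),
        )
        series = synthetic.generate_petite_time_series(
            params,
            sampling_times=config.get("sampling_times", [0.0, 3.0, 6.0, 9.0]),
            colonies_per_plate=config.get("colonies_per_plate", 150),
            n_replicates=config.get("n_replicates", 8),
            baseline_fraction=config.get("baseline_fraction", 0.05),
            seed=s_series,
        )
        write_series_tsv(series, out / "petite_series.tsv")
        report["outputs"]["petite_series"] = "petite_series.tsv"

        rng = np.random.default_rng(s_plate)
        rates = rng.uniform(0.1, 0.6, size=config.get("n_curves", 8))
        curves = [
            synthetic.generate_growth_curve(
                rate=float(rt), seed=int(s_plate + i), curve_id=f"well{i + 1:02d}"
            )
            for i, rt in enumerate(rates)
        ]
        plate = pd.DataFrame({"time_min": curves[0].times_min})
        for c in curves:
            plate[c.curve_id] = c.od600
        plate.to_csv(out / "plate.csv", index=False)
        report["outputs"]["plate"] = "plate.csv"
        report["true_rates"] = {c.curve_id: float(r) for c, r in zip(curves, rates)}

        colonies = synthetic.generate_colony_areas(
            n=config.get("n_colonies", 200),
            petite_fraction=config.get("petite_fraction", 0.3),
            label_noise=config.get("label_noise", 0.0),
            seed=s_colony,
        )
        colonies.to_csv(out / "colonies.csv", index=False)
        report["outputs"]["colonies"] = "colonies.csv"

        cm = synthetic.generate_screen_counts(
            n_genes=config.get("n_genes", 200),
            n_reps=config.get("n_reps", 3),
            library_size=config.get("library_size", 50_000),
            spike_effects=config.get("spike_effects"),
            dispersion=config.get("dispersion", 0.0),
            seed=s_counts,
        )
        write_counts_tsv(cm.counts, out / "counts.tsv")
        cm.samples.to_csv(out / "samples.tsv", sep="\t", index_label="sample_id")
        report["outputs"]["counts"] = "counts.tsv"
        report["outputs"]["samples"] = "samples.tsv"

    elif workflow == "loss_rate":
        series = read_series_tsv(config["series_tsv"])
        est = estimate_loss_rate(
            series,
            g_wt=config.get("g_wt", 0.4),
            g_mut=config.get("g_mut", 0.4),
            fit_f0=config.get("fit_f0", True),
            n_boot=config.get("n_boot", 1000),
            seed=seed,
        )
        summary = None
        if "genotype" in series.columns:
            from .petite import petite_fraction_summary

            summary = petite_fraction_summary(series)
            summary.to_csv(out / "petite_summary.tsv", sep="\t", index=False,
                           na_rep="NA")
            report["outputs"]["summary"] = "petite_summary.tsv"
        report["loss_rate"] = {
            "r_hat_per_h": est.r_hat,
            "f0_hat": est.f0_hat,
            "ci_lower": est.ci_lower,
            "ci_upper": est.ci_upper,
            "ci_level": est.ci_level,
            "n_boot": est.n_boot,
            "at_boundary": est.at_boundary,
            "method": est.method,
            "note": (
                "petite fraction at plating identified with rho0 fraction; "
                "no correction for post-plating mtDNA loss"
            ),
        }

    elif workflow == "screen":
        sample_sheet = read_index_tsv(config["index_tsv"])
        if "fastq" in config:
            gene_map = read_gene_barcode_tsv(config["gene_barcode_tsv"])
            layout = ReadLayout(**config.get("layout", {}))
            maps = BarcodeMaps(
                gene_map=gene_map,
                index_map=dict(zip(sample_sheet["sample_id"], sample_sheet["index"])),
                layout=layout,
            )
            counts, stats = demultiplex_counts(config["fastq"], maps)
            write_counts_tsv(counts, out / "counts.tsv")
            with open(out / "discard_stats.json", "w") as fh:
                json.dump(stats.as_dict(), fh, indent=2)
            report["outputs"]["counts"] = "counts.tsv"
            report["outputs"]["discard_stats"] = "discard_stats.json"
            report["demux"] = stats.as_dict()
        else:
            counts = read_counts_tsv(config["counts_tsv"])
        samples = sample_sheet.set_index("sample_id")[["condition", "replicate"]]
        cm = CountMatrix(counts=counts, samples=samples)
        scfg = ScreenConfig(fdr=config.get("fdr", 0.05),
                            dispersion=config.get("dispersion", 0.0))
        report["contrasts"] = {}
        for name, pair in _contrasts_from_config(config, cm):
            res = run_contrast(cm, pair, scfg)
            res.to_csv(out / f"results_{name}.tsv", sep="\t", na_rep="NA")
            hits = select_hits(res, mode="fdr", fdr=scfg.fdr)
            report["contrasts"][name] = {
                "conditions": list(pair),
                "n_significant": int(res["significant"].sum()),
                "fdr": scfg.fdr,
                "hits": hits,
            }
            report["outputs"][f"results_{name}"] = f"results_{name}.tsv"
    else:
        raise ValidationError(f"unknown workflow {workflow!r}")

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def _contrasts_from_config(config: dict, cm: CountMatrix):
    named = {
        "etbr_vs_control": ("etbr", "control"),
        "outgrowth_vs_etbr": ("outgrowth", "etbr"),
    }
    requested = config.get("contrasts")
    if requested is None:
        conds = set(cm.samples["condition"])
        requested = [n for n, pair in named.items() if set(pair) <= conds]
        if not requested:
            raise ValidationError("no applicable contrast for sample conditions")
    out = []
    for item in requested:
        if isinstance(item, str):
            if item not in named:
                raise ValidationError(f"unknown contrast {item!r}")
            out.append((item, named[item]))
        else:
            a, b = item
            out.append((f"{a}_vs_{b}", (a, b)))
    return out
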