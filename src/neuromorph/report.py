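"""End-to-end pipeline over a study directory.

Reads the study layout written by :func:`neuromorph.synthdata.generate_study`
(or user-supplied equivalents), measures every sample at both scales and
writes tabular outputs: per-sample morphometrics, per-group summaries,
per-sample lattice statistics, law tables, and a JSON mirror.  A failing
sample is logged and skipped, never aborting the run.  Outputs are
byte-stable for identical inputs (no timestamps inside files).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import lattice as _lat
from . import morphometry as _morph
from .surfaces import Plane, read_landmarks, read_mesh

logger = logging.getLogger("neuromorph")

__all__ = ["PipelineRun", "run_pipeline", "compare_groups"]


@dataclass
class PipelineRun:
    study_dir: Path
    out_dir: Path
    config_hash: str
    successes: list[str] = field(default_factory=list)
    failures: dict[str, str] = field(default_factory=dict)


def _plane_from_manifest(manifest: dict) -> Plane:
    sp = manifest.get("split_plane", {})
    return Plane(point=np.asarray(sp.get("point", [0, 0, 0]), float),
                 normal=np.asarray(sp.get("normal", [1, 0, 0]), float))


def run_pipeline(study_dir, out_dir, aboav_form: str = "standard",
                 do_test: bool = False, plots: bool = False,
                 lobe_thickness: bool = False) -> PipelineRun:
    """Measure every sample of a study and write all report tables.

    Outputs in ``out_dir``: ``morphometrics.csv`` (one row per sample),
    ``group_summary.csv`` (one row per metric x genotype),
    ``lattice_stats.csv`` (one row per sample with a label image),
    ``law_tables.csv`` (one row per polygon class per sample),
    ``summary.json`` (everything, plus the run log) and ``run.log``.
    Optional ``--plots``-style dot plots and distributions as PNG.
    """
    study_dir = Path(study_dir)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest_path = study_dir / "manifest.json"
    if not manifest_path.is_file():
        raise IOError(f"missing manifest: {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    plane = _plane_from_manifest(manifest)
    config_hash = hashlib.sha256(
        json.dumps(manifest.get("config", {}), sort_keys=True).encode()
    ).hexdigest()[:16]
    run = PipelineRun(study_dir, out_dir, config_hash)

    records = []
    lattice_rows = []
    law_rows = []
    log_lines = []
    for entry in manifest["samples"]:
        sid = entry["sample_id"]
        sdir = study_dir / entry.get("dir", sid)
        try:
            sample = _morph.BrainSample(
                sample_id=sid,
                genotype=entry["genotype"],
                cortex_outer=read_mesh(sdir / "cortex_outer.ply"),
                ventricular_surface=read_mesh(sdir / "ventricular.ply"),
                pupils=tuple(read_landmarks(sdir / "landmarks.csv")[:2]),
            )
            rec = _morph.analyze_sample(sample, plane,
                                        lobe_thickness=lobe_thickness)
            records.append(rec)
        except Exception as exc:
            run.failures[sid] = f"morphometry: {exc}"
            log_lines.append(f"FAIL {sid}: morphometry: {exc}")
            logger.warning("sample %s failed: %s", sid, exc)
            continue
        run.successes.append(sid)
        log_lines.append(f"OK   {sid}")

        labels_path = sdir / "labels.tif"
        if labels_path.is_file():
            try:
                truth = json.loads((sdir / "truth.json").read_text()) \
                    if (sdir / "truth.json").is_file() else {}
                px = truth.get("lattice", {}).get("pixel_size", 1.0)
                img = _lat.LabelImage(tifffile.imread(labels_path), px)
                cl = _lat.adjacency_from_labels(img)
                stats = _lat.interior_stats(cl)
                lattice_rows.append(_lattice_row(sid, entry["genotype"], stats))
                try:
                    tables = _lat.empirical_law_tables(
                        stats, aboav_form=aboav_form)
                    law_rows.append(tables.to_frame().assign(
                        sample_id=sid, genotype=entry["genotype"],
                        lewis_slope=tables.lewis_fit.slope,
                        lewis_intercept=tables.lewis_fit.intercept,
                        aboav_slope=tables.aboav_fit.slope,
                        aboav_intercept=tables.aboav_fit.intercept))
                except ValueError as exc:
                    log_lines.append(f"NOTE {sid}: law tables skipped: {exc}")
            except Exception as exc:
                run.failures[sid] = f"lattice: {exc}"
                log_lines.append(f"FAIL {sid}: lattice: {exc}")

    if not records:
        raise RuntimeError("no sample could be analysed; see run.log")

    morpho = _records_frame(records)
    morpho.to_csv(out_dir / "morphometrics.csv", index=False)
    summaries = _morph.summarize_groups(records)
    summary_df = _morph.summaries_to_frame(summaries)
    summary_df.to_csv(out_dir / "group_summary.csv", index=False)

    if lattice_rows:
        pd.DataFrame(lattice_rows).to_csv(out_dir / "lattice_stats.csv",
                                          index=False)
    if law_rows:
        pd.concat(law_rows, ignore_index=True).to_csv(
            out_dir / "law_tables.csv", index=False)

    diff = None
    genos = summary_df["genotype"].unique()
    if len(genos) == 2:
        diff = compare_groups(summary_df, records=records if do_test else None)
        diff.to_csv(out_dir / "group_differences.csv", index=False)

    summary = {
        "config_hash": config_hash,
        "n_samples": len(run.successes),
        "failures": run.failures,
        "group_summary": summary_df.to_dict(orient="records"),
        "group_differences": (diff.to_dict(orient="records")
                              if diff is not None else None),
        "lattice_stats": lattice_rows,
    }
    (out_dir / "summary.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True))
    (out_dir / "run.log").write_text("\n".join(log_lines) + "\n")

    if plots:
        _make_plots(morpho, lattice_rows, out_dir)
    return run


def _records_frame(records) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "sample_id": r.sample_id,
            "genotype": r.genotype,
            "brain_volume": r.brain_volume,
            "cortical_volume": r.cortical_volume,
            "brain_area": r.brain_area,
            "cortical_thickness": r.cortical_thickness,
            "intraocular_distance": r.intraocular_distance,
            "ventricle_volume_left": r.ventricle_volumes[0],
            "ventricle_volume_right": r.ventricle_volumes[1],
            "ventricle_area_left": r.ventricle_areas[0],
            "ventricle_area_right": r.ventricle_areas[1],
            "ventricle_sphericity_left": r.sphericity_per_ventricle[0],
            "ventricle_sphericity_right": r.sphericity_per_ventricle[1],
        }
        if r.cortical_thickness_lobes is not None:
            row["cortical_thickness_left"] = r.cortical_thickness_lobes[0]
            row["cortical_thickness_right"] = r.cortical_thickness_lobes[1]
        rows.append(row)
    return pd.DataFrame(rows)


def _lattice_row(sid: str, genotype: str, stats: _lat.LatticeStats) -> dict:
    freq = stats.neighbour_frequencies
    return {
        "sample_id": sid,
        "genotype": genotype,
        "n_interior_cells": stats.n_cells_interior,
        "mean_neighbour_number": stats.mean_neighbour_number,
        "hexagon_fraction": freq.get(6, 0.0),
        "heptagon_fraction": freq.get(7, 0.0),
        "pentagon_fraction": freq.get(5, 0.0),
        "mean_area_um2": stats.mean_area,
        "mean_aspect_ratio": (float(np.mean(stats.aspect_ratios))
                              if len(stats.aspect_ratios) else np.nan),
    }


def compare_groups(summary: pd.DataFrame, records=None) -> pd.DataFrame:
    """Per-metric difference table between the two genotype groups.

    Reports the two group means and HET − WT mean difference.  When per-
    sample ``records`` are supplied, a Welch t statistic and raw p-value
    are appended, labelled exploratory: the study design this emulates is
    descriptive and underpowered, so no significance claim is implied.
    """
    genos = sorted(summary["genotype"].unique())
    if len(genos) < 2:
        raise ValueError("compare_groups needs both genotypes")
    wide = summary.pivot(index="metric", columns="genotype", values="mean")
    out = wide.reset_index().rename(
        columns={"WT": "mean_WT", "HET": "mean_HET"})
    out["difference"] = out["mean_HET"] - out["mean_WT"]
    if records is not None:
        from scipy import stats as _st
        frame = _morph.records_to_frame(records)
        tcol, pcol = [], []
        for metric in out["metric"]:
            a = frame.loc[(frame.metric == metric) & (frame.genotype == "WT"),
                          "value"]
            b = frame.loc[(frame.metric == metric) & (frame.genotype == "HET"),
                          "value"]
            if len(a) >= 2 and len(b) >= 2:
                t, p = _st.ttest_ind(b, a, equal_var=False)
                tcol.append(float(t))
                pcol.append(float(p))
            else:
                tcol.append(np.nan)
                pcol.append(np.nan)
        out["welch_t_exploratory"] = tcol
        out["p_raw_exploratory"] = pcol
    return out


def _make_plots(morpho: pd.DataFrame, lattice_rows: list[dict],
                out_dir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    metrics = ["brain_volume", "brain_area", "intraocular_distance",
               "ventricle_sphericity_left", "cortical_thickness"]
    fig, axes = plt.subplots(1, len(metrics), figsize=(3 * len(metrics), 3))
    for ax, metric in zip(np.atleast_1d(axes), metrics):
        for i, geno in enumerate(("WT", "HET")):
            vals = morpho.loc[morpho.genotype == geno, metric]
            ax.plot(np.full(len(vals), i) + np.linspace(-0.05, 0.05, len(vals)),
                    vals, "o", label=geno)
        ax.set_xticks([0, 1], ["WT", "HET"])
        ax.set_title(metric, fontsize=8)
    fig.tight_layout()
    fig.savefig(out_dir / "morphometrics.png", dpi=120)
    plt.close(fig)

    if lattice_rows:
        df = pd.DataFrame(lattice_rows)
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.bar(df["sample_id"], df["mean_neighbour_number"])
        ax.axhline(6.0, color="k", ls="--", lw=1)
        ax.set_ylabel("mean neighbour number")
        ax.tick_params(axis="x", rotation=90, labelsize=6)
        fig.tight_layout()
        fig.savefig(out_dir / "lattice_stats.png", dpi=120)
        plt.close(fig)
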