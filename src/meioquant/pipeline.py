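"""End-to-end deterministic pipeline run over synthetic inputs.

Given a configuration and a seed, simulate every input type, run the
corresponding quantification stage, and write all outputs (TIFF movies,
trajectory/spot/call tables, qPCR enrichments, calibrated composite
profiles, per-residue ratios) into one directory.  Identical
configuration and seed produce byte-identical files, which is asserted
in the test suite.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import chip, classify, phospho, spots, synth
from .stack import write_tiff

DEFAULT_CONFIG: dict = {
    "n_cells": 8,
    "p_split": 0.4,
    "qpcr_rows": [[2.0, 1.0, 0.25], [1.9, 5.0, 0.1], [1.8, 10.0, 0.02]],
    "qpcr_jitter_sd": 0.05,
    "chrom_lengths": {"chrI": 20000, "chrII": 20000, "chrIII": 20000},
    "centromeres": {"chrI": 10000, "chrII": 9000, "chrIII": 11000},
    "coverage_noise_sd": 0.5,
    "counts": {"wx": 1.0e6, "ipx": 8.0e5, "wc": 2.0e5, "ipc": 2.0e5},
    "protein_length": 60,
    "peptides": [[1, 12, "nonphosphopeptide"], [10, 25, "nonphosphopeptide"],
                 [30, 45, "phosphopeptide"]],
    "log2fc": 1.0,
    "peptide_jitter_sd": 0.1,
}

_FLOAT_FMT = "%.10g"


def _dump_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)


def run_pipeline(out_dir, seed: int = 0, config: dict | None = None) -> dict:
    """Run every stage on generated inputs; write outputs to ``out_dir``.

    Returns a summary dictionary (also written as ``summary.json``).
    """
    cfg = dict(DEFAULT_CONFIG)
    if config:
        cfg.update(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- imaging: simulate movies, detect spots, classify segregation
    params = synth.SimParams(seed=seed, n_cells=int(cfg["n_cells"]),
                             p_split=float(cfg["p_split"]))
    stacks, trajectories, truth = synth.make_population(params)
    truth.to_json(out / "ground_truth.json")
    synth.trajectories_to_dataframe(trajectories).to_csv(
        out / "trajectories.csv", index=False, float_format=_FLOAT_FMT
    )
    spot_frames = []
    calls = []
    for stack, traj in zip(stacks, trajectories):
        write_tiff(stack, out / f"{traj.cell_id}.tif")
        detected_frames: list[list[classify.Focus]] = []
        for f in range(stack.n_frames):
            red = spots.z_project(stack, channel=0, frame=f)
            green = spots.z_project(stack, channel=1, frame=f)
            thr = spots.yen_threshold(red)
            recs = spots.detect_spots(red, thr, min_area=2, secondary_grid=green)
            for r in recs:
                r.frame = f
            spot_frames.extend(recs)
            detected_frames.append(
                [
                    classify.Focus(
                        y_um=r.centroid[0] * params.pixel_size,
                        x_um=r.centroid[1] * params.pixel_size,
                        intensity=r.mean_intensity_primary,
                        secondary_intensity=r.mean_intensity_secondary,
                    )
                    for r in recs[:2]
                ]
            )
        detected_traj = classify.CellTrajectory(
            cell_id=traj.cell_id,
            foci=classify.link_foci(detected_frames),
            marker_state=traj.marker_state,
            frame_interval=params.frame_interval,
        )
        call = classify.classify_heterozygous(detected_traj)
        calls.append(
            {
                "cell_id": traj.cell_id,
                "category": call.category,
                "max_distance_um": call.max_distance,
                "onset_frame": call.onset_frame,
            }
        )
    spots.spots_to_dataframe(spot_frames).to_csv(
        out / "spots.csv", index=False, float_format=_FLOAT_FMT
    )
    import pandas as pd

    calls_df = pd.DataFrame(calls)
    calls_df.to_csv(out / "calls.csv", index=False, float_format=_FLOAT_FMT)
    summary = classify.population_summary([list(calls_df["category"])])
    category_means = {
        r["category"]: r["mean"] for _, r in summary.iterrows()
    }

    # --- qPCR enrichment
    qpcr_rows = [tuple(r) for r in cfg["qpcr_rows"]]
    measurements, qpcr_truth = synth.make_qpcr_table(
        qpcr_rows, seed=seed + 1, jitter_sd=float(cfg["qpcr_jitter_sd"])
    )
    synth.qpcr_to_dataframe(measurements).to_csv(
        out / "qpcr_ct.csv", index=False, float_format=_FLOAT_FMT
    )
    enr = [chip.qpcr_enrichment(mc, mi) for mc, mi in measurements]
    pd.DataFrame(
        {"primer": [m[0].primer for m in measurements],
         "enrichment": enr, "true_enrichment": qpcr_truth}
    ).to_csv(out / "qpcr_enrichment.csv", index=False, float_format=_FLOAT_FMT)

    # --- spike-in calibrated coverage + composite profile
    chrom_lengths = {k: int(v) for k, v in cfg["chrom_lengths"].items()}
    centromeres = {k: int(v) for k, v in cfg["centromeres"].items()}
    tracks, bed, _track_truth, _warn = synth.make_coverage_tracks(
        chrom_lengths, centromeres,
        peak_shape=synth.triangular_peak(2000, 10.0),
        noise_sd=float(cfg["coverage_noise_sd"]), seed=seed + 2,
    )
    counts = chip.ChipSeqCounts(**cfg["counts"])
    ratio = chip.occupancy_ratio(counts)
    calibrated = {c: chip.calibrate_track(t, ratio) for c, t in tracks.items()}
    chip.write_bedgraph(calibrated, out / "coverage_calibrated.bedgraph")
    chip.write_bed(bed, out / "centromeres.bed")
    profile = chip.composite_median_profile(calibrated, centromeres)
    pd.DataFrame(
        {"offset_bp": profile.offsets, "median_signal": profile.median,
         "n_contributing": profile.n_contributing}
    ).to_csv(out / "composite_profile.csv", index=False, float_format=_FLOAT_FMT)

    # --- per-residue phosphopeptide aggregation
    protein_length = int(cfg["protein_length"])
    fc = np.full(protein_length, float(cfg["log2fc"]))
    peptide_spans = [(int(s), int(e), str(st)) for s, e, st in cfg["peptides"]]
    target, reference, _fc_truth = synth.make_peptide_table(
        protein_length, peptide_spans, fc,
        smc3_factors={"mutant": 1.5}, seed=seed + 3,
        jitter_sd=float(cfg["peptide_jitter_sd"]),
    )
    target.to_csv(out / "peptides.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
    residue_table = phospho.per_residue_pipeline(
        target, reference, protein_length, condition="mutant", baseline="WT"
    )
    residue_table.to_csv(out / "residue_ratios.csv", index=False, float_format=_FLOAT_FMT)

    result = {
        "seed": seed,
        "n_cells": int(cfg["n_cells"]),
        "category_fractions": category_means,
        "qpcr_enrichment": enr,
        "occupancy_ratio": ratio,
        "composite_peak_height": float(np.nanmax(profile.median)),
        "n_residues_quantified": int(residue_table["residue"].nunique()),
        "mean_residue_log2fc": float(residue_table["mean"].mean()),
    }
    _dump_json(result, out / "summary.json")
    return result
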