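"""Orchestration: simulate/load -> mine -> map -> profile -> stats -> detect.

A run is driven by a single config (YAML or dict), writes every stage
table as TSV into the output directory together with a manifest (config
hash, seed, package version, stage outputs) and a warnings sidecar, and
is byte-identical when re-run with the same config.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import simulate as sim
from .detector import detect_expmotifs, position_density
from .expression import (
    LevelThresholds,
    build_profiles,
    expressed_filter,
    read_tpm_matrix,
)
from .miner import MinerCriteria, mine_sequences, read_fasta
from .regions import (
    Region,
    TranscriptAnnotation,
    annotate_ssrs,
    read_annotation_table,
    region_bounds,
    write_annotation_table,
)
from .stats import (
    region_differential,
    summarize_dataset,
    summarize_regions,
    tidy_test_results,
)

STAGES = ("simulate", "mine", "map", "profile", "stats", "detect")


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage


def _config_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def load_run_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _region_sizes(anns: Mapping[str, TranscriptAnnotation]) -> dict[str, tuple[int, int]]:
    """Per-region (sequence count, summed bp) over all transcripts."""
    sizes: dict[str, list[int]] = {}
    for ann in anns.values():
        for region, (_, rlen) in region_bounds(ann).items():
            entry = sizes.setdefault(region.value, [0, 0])
            entry[0] += 1
            entry[1] += rlen
        if not ann.is_lncrna and not ann.has_cds:
            entry = sizes.setdefault(Region.OTHER.value, [0, 0])
            entry[0] += 1
            entry[1] += ann.length
    return {k: (v[0], v[1]) for k, v in sizes.items()}


def run_pipeline(config: dict, outdir) -> dict:
    """Execute all stages; returns the manifest (also written to disk)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config_hash": _config_hash(config),
        "seed": config.get("seed"),
        "outputs": {},
    }
    collected: list[str] = []

    def _emit(name: str, df: pd.DataFrame) -> None:
        path = outdir / name
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")
        manifest["outputs"][name] = len(df)

    criteria = MinerCriteria(
        min_repeats_by_size=tuple(
            config.get("min_repeats", MinerCriteria().min_repeats_by_size)
        ),
        max_interruption_bp=int(config.get("compound_gap", 0)),
    )

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        # --- inputs -------------------------------------------------------
        try:
            if "simulate" in config:
                scfg = sim.config_from_dict(
                    {**config["simulate"], "seed": config.get("seed", config["simulate"].get("seed"))}
                )
                seqs, anns, truth = sim.generate_transcriptome(scfg, criteria)
                tpm = sim.generate_expression(scfg, truth, anns)
                sim.write_fasta(seqs, outdir / "transcripts.fasta")
                write_annotation_table(anns, outdir / "coords.tsv")
                _emit("truth.tsv", truth)
                tpm.to_csv(outdir / "tpm.tsv", sep="\t", float_format="%.6g")
                manifest["outputs"]["tpm.tsv"] = len(tpm)
            else:
                seqs = read_fasta(config["fasta"])
                anns = read_annotation_table(config["coords"])
                tpm = read_tpm_matrix(config["tpm"])
        except (KeyError, ValueError, OSError) as exc:
            raise StageError("simulate", str(exc)) from exc

        # --- mine ---------------------------------------------------------
        try:
            ssr_df = mine_sequences(seqs, criteria)
            _emit("mined.tsv", ssr_df)
        except ValueError as exc:
            raise StageError("mine", str(exc)) from exc

        # --- map ----------------------------------------------------------
        try:
            assign_df = annotate_ssrs(ssr_df, anns, sequences=seqs)
            _emit("assignments.tsv", assign_df)
        except (KeyError, ValueError) as exc:
            raise StageError("map", str(exc)) from exc

        # --- profile ------------------------------------------------------
        try:
            thresholds = LevelThresholds(
                max_cuts=tuple(config.get("max_cuts", LevelThresholds().max_cuts)),
                cv_cuts=tuple(config.get("cv_cuts", LevelThresholds().cv_cuts)),
            )
            profiles = build_profiles(tpm, thresholds)
            _emit("profiles.tsv", profiles)
        except ValueError as exc:
            raise StageError("profile", str(exc)) from exc

        # --- stats --------------------------------------------------------
        try:
            total_bp = int(sum(len(s) for s in seqs.values()))
            _emit("summary_dataset.tsv", summarize_dataset(ssr_df, len(seqs), total_bp))
            _emit("summary_regions.tsv", summarize_regions(assign_df, _region_sizes(anns)))
            expressed = profiles[
                profiles["transcript_id"].isin(
                    tpm.index[expressed_filter(tpm)].astype(str)
                )
            ]
            results = region_differential(expressed, assign_df)
            _emit("tests.tsv", tidy_test_results(results))
        except ValueError as exc:
            raise StageError("stats", str(exc)) from exc

        # --- detect -------------------------------------------------------
        try:
            lengths = {tid: ann.length for tid, ann in anns.items()}
            det = detect_expmotifs(
                assign_df,
                profiles,
                lengths,
                alpha=float(config.get("alpha", 0.05)),
                min_carriers=int(config.get("min_carriers", 10)),
                vif_threshold=float(config.get("vif_threshold", 10.0)),
            )
            for name, df in det.items():
                _emit(f"{name}.tsv", df)
            _emit("density_curves.tsv", _density_curves(det, assign_df, profiles))
        except ValueError as exc:
            raise StageError("detect", str(exc)) from exc

        collected = [str(w.message) for w in caught]

    (outdir / "warnings.log").write_text("\n".join(collected) + ("\n" if collected else ""))
    manifest["n_warnings"] = len(collected)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def _density_curves(
    det: Mapping[str, pd.DataFrame],
    assign_df: pd.DataFrame,
    profiles: pd.DataFrame,
) -> pd.DataFrame:
    """Relative-position density curves per called motif-region, by TPM level."""
    calls = det["calls_actual"]
    called = calls[calls["called"]] if len(calls) else calls
    prof = profiles.set_index(profiles["transcript_id"].astype(str))
    frames = []
    for row in called.itertuples(index=False):
        level_col = "level_max" if row.response == "ln_tpm_max" else "level_cv"
        sub = assign_df[
            (assign_df["motif"] == row.motif) & (assign_df["region"] == row.region)
        ].dropna(subset=["relative_position"])
        sub = sub[sub["transcript_id"].astype(str).isin(prof.index)]
        if sub.empty:
            continue
        levels = prof.loc[sub["transcript_id"].astype(str), level_col].to_numpy()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                curves, _peaks = position_density(
                    sub["relative_position"].to_numpy(), levels
                )
        except ValueError:
            continue
        curves.insert(0, "response", row.response)
        curves.insert(0, "region", row.region)
        curves.insert(0, "motif", row.motif)
        frames.append(curves)
    if not frames:
        return pd.DataFrame(columns=["motif", "region", "response", "level", "x", "density"])
    return pd.concat(frames, ignore_index=True)
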