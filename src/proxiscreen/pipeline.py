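"""End-to-end pipeline: (simulate |) read -> filter -> score -> diff -> enrich.

Given a YAML configuration (or programmatic :class:`PipelineConfig`), runs
every stage for each condition, writes all result tables as TSV into the
output directory, and records a JSON manifest of parameters, versions and
per-stage row counts. All randomness flows through the single seed, so a
rerun with the same config reproduces every output byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import scipy
import yaml

from . import __version__
from .differential import (DifferentialParams, calls_to_frame,
                           classify_differential, normalize_bait_means,
                           venn_counts)
from .enrichment import enrich, rows_to_frame
from .errors import PipelineStageError, ValidationError
from .filtering import (FilterCriteria, apply_replicate_filter, hits_to_frame,
                        passing_set)
from .io import (read_annotations, read_count_matrix, write_annotations,
                 write_count_matrix, write_table)
from .matrix import SpectralCountMatrix
from .saint import SaintParams, high_confidence, saint_score, scores_to_frame
from .simulate import (SyntheticScreenConfig, simulate_screen,
                       synthetic_annotations, truth_to_frame)

log = logging.getLogger("proxiscreen")


@dataclass
class PipelineConfig:
    """Inputs, outputs and stage parameters for one pipeline run."""

    outdir: str = "proxiscreen_out"
    counts_path: str | None = None   # None -> simulate a screen
    meta_path: str | None = None
    gmt_path: str | None = None      # None -> synthetic annotation terms
    condition_a: str | None = None   # None -> last condition in the matrix
    condition_b: str | None = None   # None -> first condition
    seed: int = 0
    min_term_size: int = 2
    log_level: str = "INFO"
    filter_criteria: FilterCriteria = field(default_factory=FilterCriteria)
    saint_params: SaintParams = field(default_factory=SaintParams)
    differential_params: DifferentialParams = field(
        default_factory=DifferentialParams)
    simulation: SyntheticScreenConfig = field(
        default_factory=SyntheticScreenConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "PipelineConfig":
        raw = dict(raw)
        kwargs: dict[str, Any] = {}
        for section, klass in (("filter_criteria", FilterCriteria),
                               ("saint_params", SaintParams),
                               ("differential_params", DifferentialParams),
                               ("simulation", SyntheticScreenConfig)):
            if section in raw:
                sub = raw.pop(section)
                if "conditions" in sub:
                    sub["conditions"] = tuple(sub["conditions"])
                kwargs[section] = klass(**sub)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        kwargs.update(raw)
        return cls(**kwargs)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineStageError:
                raise
            except Exception as exc:
                raise PipelineStageError(name, exc) from exc
        return wrapped
    return deco


@_stage("counts-io")
def _load(config: PipelineConfig) -> SpectralCountMatrix:
    return read_count_matrix(config.counts_path, config.meta_path)


@_stage("simulate")
def _simulate(config: PipelineConfig, outdir: Path):
    sim = dataclasses.replace(config.simulation, seed=config.seed)
    matrix, truth = simulate_screen(sim)
    write_count_matrix(matrix, outdir / "counts.tsv", outdir / "meta.tsv")
    write_table(truth_to_frame(truth), outdir / "truth.tsv")
    return matrix, truth


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run every stage and return the manifest (also written as JSON)."""
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    truth = None
    if config.counts_path is None:
        matrix, truth = _simulate(config, outdir)
    else:
        if config.meta_path is None:
            raise PipelineStageError(
                "counts-io", ValidationError("meta_path required with counts_path"))
        matrix = _load(config)
    conditions = matrix.conditions()
    log.info("loaded %d proteins x %d runs (%s)", matrix.n_proteins,
             matrix.n_runs, ", ".join(conditions))

    cond_a = config.condition_a or conditions[-1]
    cond_b = config.condition_b or conditions[0]

    # -- replicate filter + SAINT-style scoring, per condition ------------
    candidates: dict[str, set[str]] = {}
    hc: dict[str, set[str]] = {}
    hit_frames, score_frames = [], []
    for cond in conditions:
        try:
            hits = apply_replicate_filter(matrix, cond, config.filter_criteria)
            candidates[cond] = passing_set(hits)
            frame = hits_to_frame(hits)
        except Exception as exc:
            raise PipelineStageError("filter", exc) from exc
        frame.insert(0, "condition", cond)
        hit_frames.append(frame)
        try:
            scores = saint_score(matrix, cond, config.saint_params)
            hc[cond] = high_confidence(scores, config.saint_params)
            sframe = scores_to_frame(scores, config.saint_params)
        except Exception as exc:
            raise PipelineStageError("score", exc) from exc
        sframe.insert(0, "condition", cond)
        score_frames.append(sframe)
        log.info("%s: %d detected -> %d candidates -> %d high-confidence",
                 cond, matrix.n_proteins, len(candidates[cond]), len(hc[cond]))
    write_table(pd.concat(hit_frames, ignore_index=True),
                outdir / "candidates.tsv")
    write_table(pd.concat(score_frames, ignore_index=True),
                outdir / "scores.tsv")

    # -- differential comparison (first two conditions) --------------------
    venn = None
    if cond_a != cond_b:
        try:
            means_a = normalize_bait_means(
                matrix, cond_a, config.differential_params.normalization)
            means_b = normalize_bait_means(
                matrix, cond_b, config.differential_params.normalization)
            calls = classify_differential(candidates[cond_a],
                                          candidates[cond_b],
                                          means_a, means_b,
                                          config.differential_params)
            venn = venn_counts(calls)
        except Exception as exc:
            raise PipelineStageError("differential", exc) from exc
        dframe = calls_to_frame(calls)
        dframe.insert(0, "condition_b", cond_b)
        dframe.insert(0, "condition_a", cond_a)
        write_table(dframe, outdir / "differential.tsv")
        log.info("differential %s vs %s: %d common, %d %s-specific, %d %s-specific",
                 cond_a, cond_b, venn[0], venn[1], cond_a, venn[2], cond_b)

    # -- term enrichment ----------------------------------------------------
    try:
        if config.gmt_path is not None:
            annotations = read_annotations(config.gmt_path)
        else:
            annotations = synthetic_annotations(
                truth, matrix.protein_ids, seed=config.seed) if truth else []
            if annotations:
                write_annotations(annotations, outdir / "annotations.gmt")
        enr_frames = []
        for cond in conditions:
            background = {pid for pid, row
                          in zip(matrix.protein_ids,
                                 matrix.counts[:, matrix.column_indices(
                                     condition=cond)])
                          if row.sum() > 0}
            cand = candidates[cond] & background
            if not annotations:
                continue
            rows = enrich(cand, background, annotations,
                          min_term_size=config.min_term_size)
            frame = rows_to_frame(rows)
            frame.insert(0, "condition", cond)
            enr_frames.append(frame)
        if enr_frames:
            write_table(pd.concat(enr_frames, ignore_index=True),
                        outdir / "enrichment.tsv")
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError("enrichment", exc) from exc

    manifest: dict[str, Any] = {
        "package": "proxiscreen",
        "version": __version__,
        "versions": {"numpy": np.__version__, "scipy": scipy.__version__,
                     "pandas": pd.__version__},
        "seed": config.seed,
        "parameters": {
            "filter_criteria": dataclasses.asdict(config.filter_criteria),
            "saint_params": dataclasses.asdict(config.saint_params),
            "differential_params": dataclasses.asdict(
                config.differential_params),
            "simulation": (dataclasses.asdict(config.simulation)
                           if config.counts_path is None else None),
        },
        "inputs": {"counts_path": config.counts_path,
                   "meta_path": config.meta_path,
                   "gmt_path": config.gmt_path},
        "n_proteins": matrix.n_proteins,
        "n_runs": matrix.n_runs,
        "conditions": conditions,
        "n_candidates": {c: len(s) for c, s in candidates.items()},
        "n_high_confidence": {c: len(s) for c, s in hc.items()},
        "venn": ({"condition_a": cond_a, "condition_b": cond_b,
                  "common": venn[0], "specific_a": venn[1],
                  "specific_b": venn[2]} if venn else None),
    }
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
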