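"""End-to-end orchestration: simulate -> normalize -> index -> incidence.

``run_pipeline`` executes the stages on a simulated cohort, writes every
intermediate as TSV plus a machine-readable ``summary.json``, and returns
the summary.  The run is fully deterministic under a fixed configuration.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .exon_index import (
    build_exon_map,
    call_incidence,
    compute_delta_index,
    one_way_anova,
    reference_interval,
)
from .fixtures import load_probe_alignments
from .io import ExpressionMatrix, write_expression_tsv, write_table
from .preprocess import rma_preprocess
from .synthetic import CASE_GROUP, REFERENCE_GROUP, default_cohort_spec, simulate_probe_intensities

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger("exonskip")


@dataclass
class RunConfig:
    """Configuration of an end-to-end synthetic-cohort run."""

    seed: int = 0
    n_reference: int = 74
    n_case: int = 279
    n_filler_probesets: int = 40
    target_exon: str = "Exon 12"
    target_probeset: str = "217422_s_at"
    ci_level: float = 0.95
    stages: tuple = ("simulate", "normalize", "index", "incidence")

    def __post_init__(self) -> None:
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")
        known = {"simulate", "normalize", "index", "incidence"}
        unknown = set(self.stages) - known
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        for name in ("n_reference", "n_case"):
            if getattr(self, name) < 2:
                raise ValueError(f"{name} must be >= 2")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        allowed = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - allowed
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in d:
            d = {**d, "stages": tuple(d["stages"])}
        return cls(**d)


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Run the configured stages, writing intermediates under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"version": __version__, "config": {**asdict(config), "stages": list(config.stages)}}
    logger.info("run config: %s", summary["config"])

    spec = default_cohort_spec(
        n_reference=config.n_reference,
        n_case=config.n_case,
        seed=config.seed,
        n_filler_probesets=config.n_filler_probesets,
    )
    dataset = None
    normalized = None

    if "simulate" in config.stages:
        dataset = simulate_probe_intensities(spec)
        write_expression_tsv(
            ExpressionMatrix(dataset.intensities, "raw"), outdir / "probe_intensities_raw.tsv"
        )
        annot = pd.DataFrame(
            {
                "probeset_id": dataset.probeset_ids,
                "exon_label": [
                    lbl if lbl is not None else ""
                    for lbl in spec.probes.exon_labels
                ],
            },
            index=dataset.probe_ids,
        )
        annot.index.name = "probe_id"
        write_table(annot, outdir / "probe_annotation.tsv")
        meta = dataset.group_labels.to_frame()
        meta.index.name = "sample_id"
        write_table(meta, outdir / "sample_metadata.tsv")
        truth = pd.DataFrame({"psi": dataset.truth["psi"]})
        truth.index.name = "sample_id"
        write_table(truth, outdir / "truth_psi.tsv")
        summary["simulate"] = {
            "n_probes": int(dataset.intensities.shape[0]),
            "n_samples": int(dataset.intensities.shape[1]),
        }

    if "normalize" in config.stages:
        if dataset is None:
            raise ValueError("normalize stage requires the simulate stage")
        res = rma_preprocess(dataset.intensities, probeset_ids=dataset.probeset_ids)
        normalized = res["probe_level"]
        write_expression_tsv(
            ExpressionMatrix(normalized, "log2"), outdir / "probe_level_log2.tsv"
        )
        write_expression_tsv(
            ExpressionMatrix(res["probeset_level"], "log2"),
            outdir / "probeset_level_log2.tsv",
        )
        params = pd.DataFrame(
            [{"sample_id": s, "mu": p.mu, "sigma": p.sigma, "alpha": p.alpha}
             for s, p in zip(normalized.columns, res["params"])]
        ).set_index("sample_id")
        write_table(params, outdir / "normexp_params.tsv")
        summary["normalize"] = {"scale_tag": "log2"}

    index_values = None
    if "index" in config.stages:
        if normalized is None or dataset is None:
            raise ValueError("index stage requires simulate and normalize stages")
        exon_map = build_exon_map(load_probe_alignments(), config.target_exon)
        probeset_probes = dataset.probeset_ids[
            dataset.probeset_ids == config.target_probeset
        ].index
        index_values = compute_delta_index(normalized.loc[probeset_probes], exon_map)
        out = pd.DataFrame(
            {"group": dataset.group_labels, "exon_index": index_values}
        )
        out.index.name = "sample_id"
        write_table(out, outdir / "exon_index.tsv")
        summary["index"] = {
            "mean_reference": float(
                index_values[dataset.group_labels == REFERENCE_GROUP].mean()
            ),
            "mean_case": float(index_values[dataset.group_labels == CASE_GROUP].mean()),
        }

    if "incidence" in config.stages:
        if index_values is None:
            raise ValueError("incidence stage requires the index stage")
        ref = index_values[dataset.group_labels == REFERENCE_GROUP]
        case = index_values[dataset.group_labels == CASE_GROUP]
        interval = reference_interval(ref, level=config.ci_level)
        result = call_incidence(case, interval)
        anova = one_way_anova([ref.dropna(), case.dropna()])
        summary["incidence"] = {
            "reference_interval": list(result.reference_interval),
            "n_cases": result.n_cases,
            "n_below": result.n_below,
            "incidence_percent": result.percent,
            "incidence_ci": list(result.incidence_ci),
            "anova_f": anova.f_statistic,
            "anova_p": anova.p_value,
        }

    with (outdir / "summary.json").open("w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    logger.info("pipeline complete: %s", outdir / "summary.json")
    return summary
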