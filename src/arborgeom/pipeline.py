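"""End-to-end orchestration: configuration, batch runs, tabular outputs.

The defaults reproduce the reference analysis settings throughout: 1 μm
sampling, alpha = 0.05 (Bonferroni-corrected over the six class tests),
10% node-removal probability and 20 replicates for the perturbation
experiment, chord-parameter curvature formulas, and equal-weight pooling
of segment means into per-neuron class values.  All randomness flows from
a single base seed so every run is reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import stats as st
from .decompose import decompose_arbor
from .frenet import DEFAULT_VARIANT, arbor_geometry
from .swc import NeuronTree, read_swc

__all__ = ["RunConfig", "load_trees", "segment_table", "geometry_table", "run_compare"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Settings for a full analysis run (defaults = reference settings)."""

    spacing: float = 1.0            # μm between geometry samples
    max_lag: int = 10               # largest autocorrelation lag tested, μm
    alpha: float = 0.05             # family-wise level for the six sign tests
    curvature_variant: str = DEFAULT_VARIANT  # "chord" | "speed-invariant"
    pooling: str = "segment-mean"   # "segment-mean" | "length-weighted"
    p_remove: float = 0.1           # node-dropout probability (perturbation)
    replicates: int = 20            # perturbation replicates
    base_seed: int = 0              # root of all randomness

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_trees(paths: Iterable[str | os.PathLike]) -> tuple[list[NeuronTree], int]:
    """Read SWC files, skipping (and logging) unreadable ones.

    Returns the trees plus the number of failures.
    """
    trees: list[NeuronTree] = []
    n_failed = 0
    for path in paths:
        try:
            trees.append(read_swc(path))
        except (OSError, ValueError) as exc:
            n_failed += 1
            logger.error("skipping %s: %s", path, exc)
    return trees, n_failed


def segment_table(trees: Sequence[NeuronTree]) -> pd.DataFrame:
    """One row per segment: neuron_id, seg_class, n_points, L."""
    rows = []
    for tree in trees:
        for seg in decompose_arbor(tree):
            rows.append(
                {
                    "neuron_id": seg.neuron_id,
                    "seg_class": seg.seg_class,
                    "n_points": seg.n_points,
                    "L_um": seg.L,
                }
            )
    return pd.DataFrame(rows)


def geometry_table(trees: Sequence[NeuronTree], config: RunConfig) -> pd.DataFrame:
    """One row per 1 μm (or ``config.spacing``) geometry sample."""
    frames = []
    for tree in trees:
        for series in arbor_geometry(
            tree, spacing=config.spacing, variant=config.curvature_variant
        ):
            frames.append(series.to_frame())
    return pd.concat(frames, ignore_index=True)


def run_compare(
    trees: Sequence[NeuronTree], config: RunConfig, perturb: bool = False
) -> dict:
    """Full cohort analysis.

    Returns a dict with the per-neuron class-value table, the six sign-test
    results, autocorrelation summaries for both parameters, the 6x6
    ordering table, and (with ``perturb=True``) the per-replicate sign-test
    results of the node-dropout experiment.
    """
    if len(trees) < 2:
        raise ValueError(
            f"cohort comparison needs at least 2 neurons, got {len(trees)}"
        )
    logger.info(
        "comparing %d neurons (spacing=%g, variant=%s, pooling=%s, alpha=%g)",
        len(trees), config.spacing, config.curvature_variant,
        config.pooling, config.alpha,
    )
    geometry = st.cohort_geometry(
        trees, spacing=config.spacing, variant=config.curvature_variant
    )
    table = st.class_value_table(geometry, pooling=config.pooling)
    comparisons = st.run_class_comparisons(table, alpha=config.alpha)
    all_series = [s for segs in geometry.values() for s in segs]
    autocorr = {
        parameter: st.autocorr_analysis(
            all_series, parameter, max_lag=config.max_lag, alpha=config.alpha
        )
        for parameter in st.PARAMETERS
    }
    ordering = st.ordering_counts(table)
    out = {
        "config": config.to_dict(),
        "class_values": table,
        "comparisons": comparisons,
        "autocorrelation": autocorr,
        "ordering": ordering,
    }
    if perturb:
        out["perturbation"] = st.perturbation_experiment(
            trees,
            p_remove=config.p_remove,
            replicates=config.replicates,
            base_seed=config.base_seed,
            spacing=config.spacing,
            variant=config.curvature_variant,
            pooling=config.pooling,
            alpha=config.alpha,
        )
    return out


def compare_summary_json(results: dict) -> dict:
    """JSON-serializable summary of a :func:`run_compare` result."""
    comp = [
        {
            "parameter": r.parameter,
            "pair": list(r.pair),
            "n_pos": r.n_pos,
            "n_neg": r.n_neg,
            "n_tie": r.n_tie,
            "direction": r.direction,
            "p_value": r.p_value,
            "p_adjusted": r.p_adjusted,
            "significant": r.significant,
            "alpha_corrected": r.alpha_corrected,
        }
        for r in results["comparisons"]
    ]
    ordering = results["ordering"]
    out = {
        "config": results["config"],
        "n_neurons": int(len(results["class_values"])),
        "comparisons": comp,
        "ordering": {
            "labels": ordering.labels,
            "counts": ordering.counts.tolist(),
            "n_excluded": ordering.n_excluded,
            "modal_cell": list(ordering.modal_cell()),
        },
        "autocorrelation": {
            parameter: {
                "significant_lags": res.significant_lags(),
                "n_excluded": res.n_excluded,
            }
            for parameter, res in results["autocorrelation"].items()
        },
    }
    if "perturbation" in results:
        out["perturbation"] = [
            [
                {
                    "parameter": r.parameter,
                    "pair": list(r.pair),
                    "direction": r.direction,
                    "p_value": r.p_value,
                    "significant": r.significant,
                }
                for r in replicate
            ]
            for replicate in results["perturbation"]
        ]
    return out


def write_compare_outputs(results: dict, out_dir: str | os.PathLike) -> None:
    """Write CSV/JSON artifacts of a comparison run into ``out_dir``."""
    os.makedirs(out_dir, exist_ok=True)
    table: pd.DataFrame = results["class_values"]
    flat = table.copy()
    flat.columns = [f"{p}_{c}" for p, c in table.columns]
    flat.index.name = "neuron_id"
    flat.to_csv(os.path.join(out_dir, "class_values.csv"))
    st.comparisons_to_frame(results["comparisons"]).to_csv(
        os.path.join(out_dir, "comparisons.csv"), index=False
    )
    for parameter, res in results["autocorrelation"].items():
        res.to_frame().to_csv(
            os.path.join(out_dir, f"autocorr_{parameter}.csv"), index=False
        )
    results["ordering"].to_frame().to_csv(
        os.path.join(out_dir, "ordering_counts.csv")
    )
    with open(os.path.join(out_dir, "summary.json"), "w") as fh:
        json.dump(compare_summary_json(results), fh, indent=2, sort_keys=True)
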