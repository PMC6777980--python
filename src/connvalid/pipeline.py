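"""End-to-end validation pipeline: normalize, associate, probe, detect.

``run_validation`` drives the full comparison of one tractography count
matrix against one retrograde-tracing count matrix from a single config
mapping (or YAML file): FLN/FS normalization, Spearman and log-Pearson
association with bootstrap CIs, distance-partialed Spearman, removal
curves in both directions, and the detection sweep.  All randomness
flows from a single top-level seed fanned out via ``SeedSequence``.

``simulate_and_validate`` chains the synthetic generator into the same
pipeline, writing simulated inputs (and the latent truth) to disk so the
validation runs exactly as it would on real data.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .association import (
    bootstrap_ci,
    build_edge_table,
    partial_spearman_distance,
    sort_by_labels,
)
from .core import WeightedConnectome
from .detection import DEFAULT_DENSITIES, detection_sweep
from .normalization import (
    add_pseudocount,
    compute_fln,
    fractional_scaling,
    log_weights,
    symmetrize,
)
from .robustness import DEFAULT_FRACTIONS, removal_curve
from .synthetic import SyntheticConfig, load_defaults, simulate_experiment

logger = logging.getLogger(__name__)

__all__ = ["run_validation", "simulate_and_validate"]


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _load_config(config: dict | str | Path) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            return yaml.safe_load(fh)
    return dict(config)


def _result_row(res, mode: str, seed) -> dict:
    return dict(
        method=res.method, mode=mode, coefficient=res.coefficient,
        p=res.p_value, ci_low=res.ci_low, ci_high=res.ci_high,
        n_edges=res.n_edges, seed=seed,
    )


def run_validation(config: dict | str | Path, output_dir: str | Path | None = None) -> dict:
    """Run the full tracing-vs-tractography validation from a config.

    Config keys: ``regions``, ``tracing``, ``tractography`` (file
    paths), ``modes`` (subset of ``[symmetric, directed]``), ``seed``,
    and optionally ``n_boot``, ``ci_level``, ``fractions``,
    ``densities``, ``output_dir``.  Returns the report dict; when an
    output directory is given, also writes tidy CSV tables and a JSON
    summary carrying input hashes and the seed.
    """
    cfg = _load_config(config)
    defaults = load_defaults()["analysis"]
    for key in ("regions", "tracing", "tractography"):
        if key not in cfg:
            raise ValueError(f"config is missing required key {key!r}")
        if not Path(cfg[key]).exists():
            raise FileNotFoundError(f"{key} file not found: {cfg[key]}")
    seed = int(cfg.get("seed", 0))
    n_boot = int(cfg.get("n_boot", defaults["n_boot"]))
    level = float(cfg.get("ci_level", defaults["ci_level"]))
    modes = list(cfg.get("modes", ["symmetric", "directed"]))
    fractions = tuple(cfg.get("fractions", DEFAULT_FRACTIONS))
    densities = tuple(cfg.get("densities", DEFAULT_DENSITIES))
    output_dir = output_dir or cfg.get("output_dir")

    t0 = time.perf_counter()
    regions = cio.read_region_set(cfg["regions"])
    tracing_counts = cio.read_connectome(cfg["tracing"], regions, kind="count", directed=True)
    tract_counts = cio.read_connectome(cfg["tractography"], regions, kind="count", directed=False)
    logger.info("load: %d regions in %.2fs", regions.n, time.perf_counter() - t0)

    dists = cio.euclidean_distances(regions) if regions.centroids is not None else None

    # normalizations
    fln = compute_fln(tracing_counts)
    fln_sym = symmetrize(fln)
    fs = fractional_scaling(tract_counts)
    # pseudocount pathway for log-scale analyses
    log_fln = log_weights(compute_fln(add_pseudocount(tracing_counts)))
    log_fln_sym = log_weights(symmetrize(compute_fln(add_pseudocount(tracing_counts))))
    log_fs = log_weights(fractional_scaling(add_pseudocount(tract_counts)))

    ss = np.random.SeedSequence(seed)
    rows: list[dict] = []
    curves: list[pd.DataFrame] = []
    det_tables: list[pd.DataFrame] = []
    roc_tables: list[pd.DataFrame] = []
    for mode in modes:
        t1 = time.perf_counter()
        if mode == "symmetric":
            tracing_rank, tracing_log = fln_sym, log_fln_sym
        elif mode == "directed":
            tracing_rank, tracing_log = fln, log_fln
        else:
            raise ValueError(f"unknown mode {mode!r}")
        # label-canonical edge order: statistics are then invariant to how
        # the input files happened to order the regions
        table_rank = sort_by_labels(build_edge_table(tracing_rank, fs, dists, mode=mode), regions)
        table_log = sort_by_labels(build_edge_table(tracing_log, log_fs, dists, mode=mode), regions)

        seed_sp, seed_pe = ss.spawn(2)
        rows.append(_result_row(
            bootstrap_ci(table_rank, "spearman", n_boot=n_boot, level=level, seed=seed_sp),
            mode, seed))
        rows.append(_result_row(
            bootstrap_ci(table_log, "pearson_log", n_boot=n_boot, level=level, seed=seed_pe),
            mode, seed))
        if dists is not None:
            rows.append(_result_row(partial_spearman_distance(table_log), mode, seed))

        for direction in ("strongest", "weakest"):
            rc = removal_curve(table_rank, direction=direction, fractions=fractions)
            curves.append(pd.DataFrame(dict(
                mode=mode, direction=direction, fraction=rc.fractions,
                n_remaining=rc.n_remaining, coefficient=rc.coefficients,
                p=rc.p_values,
            )))

        if mode == "symmetric":
            det = detection_sweep(fln_sym, fs, densities)
            det_tables.append(det.table.assign(mode_analysis=mode))
            roc_tables.append(det.sweep_points.assign(mode_analysis=mode))
        logger.info("mode %s: %.2fs", mode, time.perf_counter() - t1)

    report = {
        "seed": seed,
        "n_regions": regions.n,
        "inputs": {k: {"path": str(cfg[k]), "sha256": _sha256(cfg[k])}
                   for k in ("regions", "tracing", "tractography")},
        "n_boot": n_boot,
        "ci_level": level,
        "associations": rows,
        "removal_curves": pd.concat(curves, ignore_index=True).to_dict("records"),
        "detection": (pd.concat(det_tables, ignore_index=True).to_dict("records")
                      if det_tables else []),
    }
    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(rows).to_csv(out / "associations.csv", index=False)
        pd.concat(curves, ignore_index=True).to_csv(out / "removal_curves.csv", index=False)
        if det_tables:
            pd.concat(det_tables, ignore_index=True).to_csv(out / "detection.csv", index=False)
            pd.concat(roc_tables, ignore_index=True).to_csv(out / "roc_pr_points.csv", index=False)
        with open(out / "summary.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        manifest = {
            "inputs": report["inputs"], "seed": seed,
            "outputs": sorted(p.name for p in out.iterdir() if p.name != "manifest.json"),
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    return report


def simulate_and_validate(
    syn_cfg: SyntheticConfig,
    analysis_cfg: dict | None = None,
    output_dir: str | Path | None = None,
) -> dict:
    """Simulate a paired experiment, then validate it end to end.

    Writes the simulated inputs (region table, tracer counts, streamline
    counts) and the latent truth matrix under ``output_dir`` (a
    temporary directory if omitted), then runs :func:`run_validation` on
    those files so the full IO path is exercised.  Returns the report
    with the truth file recorded for parameter-recovery checks.
    """
    import tempfile

    analysis_cfg = dict(analysis_cfg or {})
    tmp = None
    if output_dir is None:
        tmp = tempfile.TemporaryDirectory()
        output_dir = tmp.name
    out = Path(output_dir)
    (out / "inputs").mkdir(parents=True, exist_ok=True)
    try:
        sim = simulate_experiment(syn_cfg)
        cio.write_region_set(sim["regions"], out / "inputs" / "regions.csv")
        cio.write_connectome(sim["tracer_counts"], out / "inputs" / "tracer_counts.csv")
        cio.write_connectome(sim["tract_counts"], out / "inputs" / "streamline_counts.csv")
        cio.write_connectome(sim["truth"], out / "inputs" / "truth_weights.csv")
        analysis_cfg.setdefault("seed", syn_cfg.seed)
        analysis_cfg.update(
            regions=str(out / "inputs" / "regions.csv"),
            tracing=str(out / "inputs" / "tracer_counts.csv"),
            tractography=str(out / "inputs" / "streamline_counts.csv"),
        )
        report = run_validation(analysis_cfg, output_dir=out)
        report["synthetic_config"] = sim["config"]
        report["truth_file"] = str(out / "inputs" / "truth_weights.csv")
        return report
    finally:
        if tmp is not None:
            tmp.cleanup()
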