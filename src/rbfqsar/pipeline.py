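"""End-to-end orchestration: prune -> split -> screen -> optimize x M ->
consensus -> validate -> applicability domain.

Every stochastic stage receives an explicit seed derived deterministically
from the run's global seed, and the run writes a machine-readable manifest
of seeds, versions and artifacts.  Validation rows never influence any
stage before external validation.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .appdomain import ad_report, coverage
from .consensus import build_pool, select_submodels, stability_sweep
from .datatable import DescriptorTable, load_table, prune_descriptors
from .importance import mdi_importance
from .joint import JointRBFSelector
from .splitting import som_split
from .validation import validation_report

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline knobs, defaulting to the full-budget settings."""

    input_path: str | None = None
    endpoint_column: str = "endpoint"
    id_column: str = "compound_id"
    output_dir: str = "rbfqsar_run"
    seed: int = 0

    corr_threshold: float = 0.85
    som_nodes: int = 9
    som_iterations: int = 300
    pick_position: int = 3

    screen_repeats: int = 50
    screen_draws: int = 100
    screen_threshold: float = 0.01
    screen_max_neurons: int = 500

    population: int = 30
    iterations: int = 1000
    lam: float = 1.0
    L: int = 10
    eps_bounds: tuple = (1e-4, 5.0)
    delta_bounds: tuple = (1e-4, 5.0)
    gap_limit: float = 0.3
    max_neurons: int = 500
    n_models: int = 20

    consensus_method: str = "D"
    stability_reps: int = 1000
    residual_limit: float = 3.0
    yrand_rounds: int = 10
    basis: str = "halfwidth"

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["eps_bounds"] = list(self.eps_bounds)
        d["delta_bounds"] = list(self.delta_bounds)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        for k in ("eps_bounds", "delta_bounds"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class RunArtifacts:
    manifest: dict
    table: DescriptorTable
    split: object
    pool: object
    consensus: object
    reports: list = field(default_factory=list)


def _stage_seeds(seed: int, n_models: int) -> dict:
    """Derive independent per-stage seeds (< 2^31) from the global seed."""
    rng = np.random.default_rng(seed)
    names = ["som", "screen", "cv", "stability", "yrand"] + [
        f"model{i}" for i in range(n_models)
    ]
    return {name: int(rng.integers(2**31)) for name in names}


def run_pipeline(config: RunConfig, table: DescriptorTable | None = None) -> RunArtifacts:
    """Run the whole modeling pipeline; returns artifacts and writes them
    under ``config.output_dir``."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed, config.n_models)
    manifest: dict = {"version": __version__, "seed": config.seed, "seeds": seeds, "files": []}

    def _write(name, writer):
        path = out / name
        writer(path)
        manifest["files"].append(name)
        return path

    if table is None:
        if config.input_path is None:
            raise ValueError("either a table or config.input_path is required")
        table = load_table(config.input_path, config.endpoint_column, config.id_column)
    manifest["input_sha256"] = hashlib.sha256(
        table.X.tobytes() + table.y.tobytes()
    ).hexdigest()

    # 1. prune
    pruned, prune_log = prune_descriptors(table, config.corr_threshold)
    _write("prune_log.csv", prune_log.write_csv)
    logger.info("prune: %d -> %d descriptors", table.n_descriptors, pruned.n_descriptors)

    # 2. split
    split = som_split(
        pruned, config.som_nodes, config.som_iterations, config.pick_position,
        seed=seeds["som"],
    )
    _write("split.csv", lambda p: split.to_dataframe(pruned.compound_ids).to_csv(p, index=False))
    train = pruned.subset_rows(split.train_indices)
    valid = pruned.subset_rows(split.valid_indices)
    logger.info("split: %d train / %d valid", train.n_compounds, valid.n_compounds)

    # 3. screen (training data only)
    imp = mdi_importance(
        train,
        n_repeats=config.screen_repeats,
        n_param_draws=config.screen_draws,
        threshold=config.screen_threshold,
        max_neurons=config.screen_max_neurons,
        seed=seeds["screen"],
    )
    _write("importance.csv", lambda p: imp.to_dataframe().to_csv(p, index=False))
    selected = sorted(imp.retained)
    if len(selected) < 2:
        raise RuntimeError("screening stage retained fewer than 2 descriptors")
    train_s = train.subset_columns(selected)
    valid_s = valid.subset_columns(selected)
    logger.info("screen: retained %d descriptors", len(selected))

    # 4. joint optimization x n_models
    fitted, rows = [], []
    for i in range(config.n_models):
        sel = JointRBFSelector(
            population=config.population,
            iterations=config.iterations,
            lam=config.lam,
            L=config.L,
            eps_bounds=config.eps_bounds,
            delta_bounds=config.delta_bounds,
            gap_limit=config.gap_limit,
            max_neurons=config.max_neurons,
            basis=config.basis,
            seed=seeds[f"model{i}"],
        ).fit(train_s.X, train_s.y)
        fitted.append((sel.model_, sel.mask_, sel.eps_, sel.delta_))
        # validate the refitted model on its own descriptor subset
        Xtr_m = np.ascontiguousarray(train_s.X[:, sel.mask_])
        Xva_m = np.ascontiguousarray(valid_s.X[:, sel.mask_])
        rep = validation_report(
            sel.model_, Xtr_m, train_s.y, Xva_m, valid_s.y,
            mse_goal=sel.eps_, spread=sel.delta_,
            n_descriptors=int(sel.mask_.sum()),
            max_neurons=config.max_neurons, cv_seed=seeds["cv"],
            yrand_rounds=config.yrand_rounds if i == 0 else 0,
            yrand_seed=seeds["yrand"], basis=config.basis,
        )
        rows.append(
            {
                "model": i + 1,
                "eps": sel.eps_,
                "delta": sel.delta_,
                "n_descriptors": int(sel.mask_.sum()),
                "r2": rep.r2,
                "r2_adj": rep.r2_adj,
                "r2_cv10": rep.r2_cv10,
                "r2_ext": rep.r2_ext,
                "q2_ext": rep.q2_ext,
            }
        )
        name = f"model_{i + 1:02d}.json"
        _write(name, lambda p, s=sel: s.model_.save(
            p, [train_s.descriptor_names[j] for j in s.support_]
        ))
        logger.info(
            "model %d: eps=%.4g delta=%.4g p=%d R2=%.4f R2cv10=%.4f Q2ext=%.4f",
            i + 1, sel.eps_, sel.delta_, int(sel.mask_.sum()),
            rep.r2, rep.r2_cv10, rep.q2_ext,
        )
    summary = pd.DataFrame(rows)
    _write("model_summary.csv", lambda p: summary.to_csv(p, index=False))
    model_reports = rows

    # 5. consensus
    pool = build_pool(
        fitted, train_s.X, train_s.y, valid_s.X, valid_s.y,
        cv_seed=seeds["cv"], max_neurons=config.max_neurons, basis=config.basis,
    )
    cm, chosen = select_submodels(pool, config.consensus_method)
    cons_metrics = pool.metrics(chosen)
    _write(
        "consensus_summary.csv",
        lambda p: pd.DataFrame(
            [{"method": config.consensus_method, "n_submodels": len(chosen), **cons_metrics}]
        ).to_csv(p, index=False),
    )
    if pool.size >= 3:
        sweep = stability_sweep(
            pool, range(2, pool.size), reps=config.stability_reps, seed=seeds["stability"]
        )
        _write("stability_sweep.csv", lambda p: sweep.to_csv(p, index=False))

    # 6. applicability domain + outliers
    report = ad_report(
        cm, train_s.X, train_s.y, valid_s.X, valid_s.y,
        train_s.compound_ids, valid_s.compound_ids,
    )
    _write("williams.csv", lambda p: report.to_dataframe().to_csv(p, index=False))
    cov = {"fwd": coverage(report, "fwd"), "leverage": coverage(report, "leverage")}
    _write(
        "ad_summary.json",
        lambda p: Path(p).write_text(
            json.dumps(
                {
                    "warning_leverage": report.warning_leverage,
                    "fwd_threshold": report.fwd_threshold,
                    "coverage": cov,
                    "n_outliers": int(len(report.outliers)),
                },
                indent=2,
            )
        ),
    )

    manifest["consensus"] = {k: float(v) for k, v in cons_metrics.items()}
    manifest["coverage"] = cov
    manifest["models"] = model_reports
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return RunArtifacts(manifest, pruned, split, pool, cm, model_reports)
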