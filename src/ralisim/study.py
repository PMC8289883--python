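"""Orchestration of the full Monte-Carlo linking experiment.

The design crosses three between-sample factors - model fit (Rasch-conform
vs. moderate 2PL misfit), number of anchor items (3/5/7/9 of 25) and sample
size (500 / 3,000) - into 16 data-generating conditions; the four linking
methods are a within-sample factor evaluated on the *same* generated data,
giving 64 evaluation cells.  Each condition is replicated (100 times by
default) with an independent, reproducible random substream per
(condition, replication), so results are bit-identical for a fixed master
seed regardless of execution order or worker count.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from . import estimation, evaluation, linking, simulate
from .estimation import CalibrationSpec, fit_mml_em
from .linking import METHODS, run_concurrent, run_fpc, run_separate_linking
from .simulate import (
    ConfigurationError,
    StudyDesign,
    build_item_banks,
    draw_abilities,
    restrict_anchors,
    simulate_responses,
    substream_rng,
)

REPLICATIONS_FILE = "replications.csv"
META_FILE = "run_meta.json"


@dataclass(frozen=True)
class StudyConfig:
    """Full experiment specification; defaults are the study design."""

    true_means: tuple[float, ...] = (0.0, 0.7, 1.2, 1.5)
    form_length: int = 25
    alpha_sd: float = 0.14
    methods: tuple[str, ...] = METHODS
    misfit_conditions: tuple[bool, ...] = (False, True)
    anchor_counts: tuple[int, ...] = (3, 5, 7, 9)
    sample_sizes: tuple[int, ...] = (500, 3000)
    n_replications: int = 100
    master_seed: int = 20210706
    n_nodes_separate: int = 41
    n_nodes_concurrent: int = 1000
    max_iter: int = 1000
    tol: float = 1e-4
    n_workers: int = 1
    #: redraw the item bank for every replication (default), so outcome
    #: summaries average over the item-sampling distribution; set False to
    #: realize a single bank per master seed (difficulties and
    #: discriminations drawn once, shared by every condition and replication,
    #: discriminations reset to 1 in the misfit-off arm) as an operational
    #: study with one printed item table would
    bank_per_replication: bool = True

    def __post_init__(self):
        bad = [m for m in self.methods if m not in METHODS]
        if bad:
            raise ConfigurationError(f"unknown methods: {bad}")
        bad = [k for k in self.anchor_counts if k not in simulate.ALLOWED_ANCHOR_COUNTS]
        if bad:
            raise ConfigurationError(f"unsupported anchor counts: {bad}")
        if self.n_replications < 1:
            raise ConfigurationError("n_replications must be >= 1")

    @property
    def conditions(self) -> list[tuple[bool, int, int]]:
        """The (misfit, anchor_count, sample_size) data-condition grid."""
        return [
            (m, k, n)
            for m in self.misfit_conditions
            for k in self.anchor_counts
            for n in self.sample_sizes
        ]

    def separate_spec(self) -> CalibrationSpec:
        return CalibrationSpec(
            mode="free", n_nodes=self.n_nodes_separate,
            max_iter=self.max_iter, tol=self.tol,
        )

    def design(self, misfit: bool, sample_size: int) -> StudyDesign:
        return StudyDesign(
            form_length=self.form_length,
            true_means=self.true_means,
            sample_size=sample_size,
            misfit=misfit,
            alpha_sd=self.alpha_sd,
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("true_means", "methods", "misfit_conditions", "anchor_counts",
                    "sample_sizes"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


def study_bank(config: StudyConfig, misfit: bool, anchor_count: int,
               replication: int | None = None):
    """The item bank for a condition (and its anchor id sets).

    With ``bank_per_replication`` (the default) the bank is redrawn per
    replication (``replication`` required).  Otherwise one bank is realized
    per master seed and reused across all conditions and replications:
    difficulties and discriminations are drawn once (from the misfit-arm
    generator), the misfit-off arm resets every discrimination to exactly 1,
    and the anchor-count conditions relabel unused anchor slots of the same
    bank.
    """
    if config.bank_per_replication:
        if replication is None:
            raise ConfigurationError("bank_per_replication requires a replication index")
        rng = substream_rng(config.master_seed, "bank", misfit, anchor_count,
                            replication)
        bank = build_item_banks(config.design(misfit, 1), rng)
    else:
        rng = substream_rng(config.master_seed, "bank")
        bank = build_item_banks(config.design(True, 1), rng)
        if not misfit:
            bank = simulate.ItemBank(bank.table.assign(discrimination=1.0))
    return restrict_anchors(bank, anchor_count)


def run_replication(
    config: StudyConfig,
    misfit: bool,
    anchor_count: int,
    sample_size: int,
    replication: int,
    bank=None,
    anchor_sets=None,
) -> list[dict]:
    """Generate one dataset and evaluate every requested method on it.

    Returns tidy rows (one per method x time point).  The three separate
    methods share the same free calibrations where they can: mean/mean and
    weighted mean/mean consume identical free fits, and FPC reuses the free
    fit of t1.  Estimation failures are recorded per method, never raised.
    """
    design = config.design(misfit, sample_size)
    T = design.n_timepoints
    if bank is None or anchor_sets is None:
        bank, anchor_sets = study_bank(config, misfit, anchor_count, replication)

    responses = []
    sample_means = []
    sample_vars = []
    for t in range(1, T + 1):
        rng_ab = substream_rng(config.master_seed, "abilities", misfit, anchor_count,
                               sample_size, replication, t)
        rng_resp = substream_rng(config.master_seed, "responses", misfit, anchor_count,
                                 sample_size, replication, t)
        beta = draw_abilities(design, t, rng_ab)
        sample_means.append(float(beta.mean()))
        sample_vars.append(float(beta.var(ddof=1)))
        responses.append(
            simulate_responses(beta, bank.items_for_form(t), rng_resp, timepoint=t)
        )

    free_spec = config.separate_spec()
    needs_free = any(m in config.methods for m in ("mean_mean", "weighted_mean_mean", "fpc"))
    free_fits = [fit_mml_em(r, free_spec) for r in responses] if needs_free else None

    rows: list[dict] = []
    base = dict(
        misfit=misfit, anchor_count=anchor_count, sample_size=sample_size,
        replication=replication,
    )

    def record(method: str, result: "linking.LinkResult | None"):
        for t in range(1, T + 1):
            # two notions of truth per replication: the population parameters,
            # and the realized sample's moments expressed on the common scale
            # (which is anchored at the t1 sample, so the t1 sample mean is
            # the scale origin)
            row = dict(
                base, method=method, timepoint=t,
                true_mean=config.true_means[t - 1], true_variance=1.0,
                sample_true_mean=sample_means[t - 1] - sample_means[0],
                sample_true_variance=sample_vars[t - 1],
            )
            if result is None:
                row.update(mu_hat=np.nan, sigma2_hat=np.nan, converged=False)
            else:
                row.update(
                    mu_hat=result.mu[t],
                    sigma2_hat=result.sigma2[t],
                    converged=bool(result.converged),
                )
            rows.append(row)

    for method in config.methods:
        try:
            if method in ("mean_mean", "weighted_mean_mean"):
                result = run_separate_linking(method, free_fits, anchor_sets)
            elif method == "fpc":
                result = run_fpc(responses, anchor_sets, spec=free_spec,
                                 first_fit=free_fits[0])
            elif method == "concurrent":
                result = run_concurrent(
                    responses, anchor_sets,
                    spec=CalibrationSpec(
                        mode="concurrent", n_nodes=config.n_nodes_concurrent,
                        max_iter=config.max_iter, tol=config.tol,
                    ),
                )
            else:  # pragma: no cover - guarded by StudyConfig
                raise ConfigurationError(method)
        except Exception:  # failure is an outcome, not a crash
            record(method, None)
        else:
            record(method, result)
    return rows


def run_study_frame(config: StudyConfig, progress: bool = False) -> pd.DataFrame:
    """Run the whole grid in memory and return the per-replication table."""
    tasks = [
        (m, k, n, r)
        for (m, k, n) in config.conditions
        for r in range(config.n_replications)
    ]
    rows = _run_tasks(config, tasks, progress)
    return pd.DataFrame(rows)


def _run_tasks(config: StudyConfig, tasks, progress: bool) -> list[dict]:
    if config.n_workers > 1:
        from joblib import Parallel, delayed

        chunks = Parallel(n_jobs=config.n_workers)(
            delayed(run_replication)(config, *task) for task in tasks
        )
    else:
        chunks = []
        for idx, task in enumerate(tasks):
            chunks.append(run_replication(config, *task))
            if progress and (idx + 1) % 25 == 0:
                print(f"  {idx + 1}/{len(tasks)} replications done", flush=True)
    return [row for chunk in chunks for row in chunk]


def run_study(config: StudyConfig, out_dir, progress: bool = False,
              overwrite: bool = False) -> pd.DataFrame:
    """Run (or resume) the experiment and persist results under ``out_dir``.

    Completed (condition, replication) cells found in an existing
    ``replications.csv`` are skipped unless ``overwrite`` is set; newly run
    cells are appended, so interrupted studies resume cleanly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rep_path = out_dir / REPLICATIONS_FILE

    existing = None
    done: set[tuple] = set()
    if rep_path.exists() and not overwrite:
        existing = pd.read_csv(rep_path)
        done = {
            (bool(m), int(k), int(n), int(r))
            for m, k, n, r in existing[
                ["misfit", "anchor_count", "sample_size", "replication"]
            ].drop_duplicates().itertuples(index=False)
        }

    tasks = [
        (m, k, n, r)
        for (m, k, n) in config.conditions
        for r in range(config.n_replications)
        if (m, k, n, r) not in done
    ]
    t0 = time.time()
    rows = _run_tasks(config, tasks, progress)
    new = pd.DataFrame(rows)
    table = pd.concat([existing, new], ignore_index=True) if existing is not None else new
    table.to_csv(rep_path, index=False)

    _write_summaries(table, out_dir)
    meta = {
        "config": dataclasses.asdict(config),
        "n_rows": int(len(table)),
        "n_new_replications": len(tasks),
        "wall_time_s": round(time.time() - t0, 2),
        "versions": _versions(),
    }
    with open(out_dir / META_FILE, "w") as fh:
        json.dump(meta, fh, indent=2)
    return table


def _versions() -> dict:
    import scipy

    from . import __version__

    return {
        "ralisim": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
    }


def _write_summaries(table: pd.DataFrame, out_dir: Path) -> None:
    by = ["method", "misfit", "anchor_count", "sample_size"]
    summary = evaluation.aggregate(table, by=by, truth="sample")
    mean_cols = by + ["timepoint", "n_replications",
                      "bias_mean", "relbias_mean", "rmse_mean", "mc_se_bias_mean"]
    var_cols = by + ["timepoint", "n_replications",
                     "bias_variance", "relbias_variance", "rmse_variance",
                     "mc_se_bias_variance"]
    summary[mean_cols].to_csv(out_dir / "summary_mean.csv", index=False)
    summary[var_cols].to_csv(out_dir / "summary_variance.csv", index=False)
    conv = (
        table.groupby(by, observed=True)["converged"].mean()
        .rename("convergence_rate").reset_index()
    )
    conv.to_csv(out_dir / "convergence.csv", index=False)


def summarize(results_dir, group_by: Iterable[str] = ("method",),
              truth: str = "sample") -> pd.DataFrame:
    """Aggregate a stored per-replication table by the requested factors.

    ``truth`` selects the error reference: the realized sample moments
    (default, the study's estimand) or the population parameters.
    """
    rep_path = Path(results_dir) / REPLICATIONS_FILE
    if not rep_path.exists():
        raise ConfigurationError(
            f"no {REPLICATIONS_FILE} under {results_dir}; run the study first"
        )
    table = pd.read_csv(rep_path)
    if table.empty:
        raise ConfigurationError(f"{rep_path} is empty")
    return evaluation.aggregate(table, by=list(group_by), truth=truth)


def demo_config(seed: int = 1) -> StudyConfig:
    """A 2-replication smoke configuration covering every method."""
    return StudyConfig(
        n_replications=2,
        anchor_counts=(3, 9),
        sample_sizes=(500,),
        master_seed=seed,
        n_nodes_concurrent=400,
    )
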