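"""Train–freeze–validate pipeline: simulate -> score -> thresholds ->
classify -> evaluate -> report.

Thresholds are fit on the training drug table, frozen, and applied to the
validation table; every artifact written embeds the config hash and the
seeds so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from .errors import UndefinedMeasureError
from .evaluate import evaluate_panel
from .io import (
    RunConfig,
    read_cell_responses,
    read_drug_table,
    write_report,
    write_score_table,
    write_thresholds,
)
from .metrics import EngineConfig, score_samples
from .models import PacingProtocol
from .pharm import assemble_sample_set, bootstrap_hill_samples
from .thresholds import ScoreDistribution, category_fractions, classify_score, fit_ordinal_thresholds

log = logging.getLogger(__name__)

__all__ = ["score_drug_table", "run_pipeline"]


def _engine(config: RunConfig) -> EngineConfig:
    return EngineConfig(
        model_id=config.model_id,
        protocol=PacingProtocol(
            cycle_length_ms=config.cycle_length_ms,
            n_beats=config.n_beats,
            stimulus_amplitude=config.stimulus_amplitude,
            stimulus_duration_ms=config.stimulus_duration_ms,
        ),
        multiples=tuple(config.multiples),
    )


def score_drug_table(records, config: RunConfig, responses=None, seed=None):
    """Uncertainty-quantified torsade metric scores for a drug panel.

    Per-current block parameters are bootstrapped from per-cell
    concentration-response data when available for that drug/current;
    otherwise the table's point estimates are used for every sample.
    Returns ``(distributions, n_failures_by_drug)``.
    """
    engine = _engine(config)
    seed = config.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    dists, fails = [], {}
    for record, child in zip(records, ss.spawn(len(records))):
        boot_seed, assemble_seed = child.generate_state(2)
        block_samples = {}
        if responses:
            for cur in set(r.current_id for r in responses
                           if r.drug == record.name):
                data = [r for r in responses
                        if r.drug == record.name and r.current_id == cur]
                if len(data) >= 2:
                    block_samples[cur] = bootstrap_hill_samples(
                        data, config.n_uq_samples, int(boot_seed),
                        current_id=cur)
        sample_set = assemble_sample_set(
            record, herg_samples=(), block_samples=block_samples,
            n=config.n_uq_samples, seed=int(assemble_seed))
        scores, n_failed = score_samples(record, sample_set, engine)
        fails[record.name] = n_failed
        log.info("scored %s: %d samples, %d failed", record.name,
                 len(scores), n_failed)
        dists.append(ScoreDistribution(record.name, scores, record.risk_label))
    return dists, fails


def run_pipeline(config: RunConfig):
    """Execute the full train-freeze-validate pipeline; returns the
    :class:`~cipasim.evaluate.PerformanceReport` and writes artifacts."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"config_sha256": config.sha256(), "seed": config.seed,
            "dataset_id": config.dataset_id}

    train = read_drug_table(config.training_table)
    train_resp = (read_cell_responses(config.training_responses)
                  if config.training_responses else None)
    ss = np.random.SeedSequence(config.seed)
    s_train, s_val, s_eval = ss.generate_state(3)

    train_dists, train_fails = score_drug_table(
        train, config, train_resp, seed=int(s_train))
    write_score_table(train_dists, out / "training_scores.csv", train_fails)

    th = fit_ordinal_thresholds(train_dists)
    write_thresholds(th, out / "thresholds.json",
                     dataset_id=config.dataset_id, diagnostics=meta)
    log.info("frozen thresholds: t1=%.6g t2=%.6g", th.t1, th.t2)

    if config.validation_table:
        val = read_drug_table(config.validation_table)
        val_resp = (read_cell_responses(config.validation_responses)
                    if config.validation_responses else None)
        val_dists, val_fails = score_drug_table(
            val, config, val_resp, seed=int(s_val))
    else:
        val_dists, val_fails = train_dists, train_fails
    write_score_table(val_dists, out / "validation_scores.csv", val_fails)

    # per-drug classification summary against the frozen thresholds
    import pandas as pd

    rows = []
    for d in val_dists:
        fh, fi, fl = category_fractions(d, th)
        rows.append({"drug": d.drug, "risk_label": d.risk_label,
                     "median_score": d.median(),
                     "predicted": classify_score(d.median(), th),
                     "frac_high": fh, "frac_intermediate": fi, "frac_low": fl})
    pd.DataFrame(rows).to_csv(out / "classification.csv", index=False)

    labeled = [d for d in val_dists if d.risk_label is not None]
    try:
        report = evaluate_panel(labeled, th, n_iter=config.n_eval_iters,
                                seed=int(s_eval))
    except UndefinedMeasureError as err:
        log.warning("labeled measures skipped: %s", err)
        from .evaluate import PerformanceReport

        report = PerformanceReport(meta={"skipped": str(err)})
    report.meta.update(meta)
    write_report(report, out / "report.json", extra_meta=meta)
    return report
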