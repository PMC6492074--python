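"""Readers/writers for the tabular dialects and run configuration.

Drug table CSV (one row per drug):

    drug, cmax_nM [or cmax_uM], risk_label,
    herg_kmax, herg_ku, herg_n, herg_halfmax, herg_vhalf,
    <cur>_ic50_nM [or <cur>_ic50_uM], <cur>_hill
        for <cur> in inal, ina, ical, iks, ik1, ito

Empty IC50 cells become the no-block sentinel; micromolar columns are
converted to nM on read (and the conversion logged). IC50s are stored
internally in nM throughout the package.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import SchemaError
from .models import HergDynamicParams, INERT_HERG
from .pharm import (
    RISK_CATEGORIES,
    ChannelBlock,
    DrugRecord,
    CellResponse,
    DrugSampleSet,
)
from .thresholds import ScoreDistribution, Thresholds

__all__ = [
    "read_drug_table",
    "write_drug_table",
    "read_cell_responses",
    "write_cell_responses",
    "read_sample_set",
    "write_sample_set",
    "read_score_table",
    "write_score_table",
    "read_thresholds",
    "write_thresholds",
    "write_report",
    "RunConfig",
]

log = logging.getLogger(__name__)

_CURRENT_COLS = {"inal": "INaL", "ina": "INa", "ical": "ICaL",
                 "iks": "IKs", "ik1": "IK1", "ito": "Ito"}
_HERG_COLS = ("herg_kmax", "herg_ku", "herg_n", "herg_halfmax", "herg_vhalf")


def _known_columns():
    cols = {"drug", "cmax_nM", "cmax_uM", "risk_label", *_HERG_COLS}
    for c in _CURRENT_COLS:
        cols |= {f"{c}_ic50_nM", f"{c}_ic50_uM", f"{c}_hill"}
    return cols


def read_drug_table(path) -> list[DrugRecord]:
    """Read and validate a drug block-parameter table."""
    df = pd.read_csv(path)
    unknown = set(df.columns) - _known_columns()
    if unknown:
        raise SchemaError(f"{path}: unknown column(s) {sorted(unknown)}")
    if "drug" not in df.columns:
        raise SchemaError(f"{path}: missing required column 'drug'")
    if df["drug"].duplicated().any():
        dupes = df.loc[df["drug"].duplicated(), "drug"].tolist()
        raise SchemaError(f"{path}: duplicated drug name(s) {dupes}")
    if "cmax_nM" not in df.columns and "cmax_uM" not in df.columns:
        raise SchemaError(f"{path}: missing column 'cmax_nM' (or 'cmax_uM')")

    records = []
    for _, row in df.iterrows():
        name = str(row["drug"])
        if "cmax_nM" in df.columns and not pd.isna(row.get("cmax_nM")):
            cmax = float(row["cmax_nM"])
        else:
            cmax = float(row["cmax_uM"]) * 1000.0
            log.info("drug %s: converted cmax from uM to nM", name)
        if not cmax > 0:
            raise SchemaError(f"{path}: drug {name!r} has nonpositive cmax")

        if all(c in df.columns and not pd.isna(row[c]) for c in _HERG_COLS):
            herg = HergDynamicParams(
                kmax=float(row["herg_kmax"]), ku=float(row["herg_ku"]),
                n=float(row["herg_n"]), halfmax=float(row["herg_halfmax"]),
                vhalf=float(row["herg_vhalf"]),
            )
        else:
            herg = INERT_HERG

        blocks = {}
        for col, cur in _CURRENT_COLS.items():
            ic50 = math.inf
            if f"{col}_ic50_nM" in df.columns and not pd.isna(row[f"{col}_ic50_nM"]):
                ic50 = float(row[f"{col}_ic50_nM"])
            elif f"{col}_ic50_uM" in df.columns and not pd.isna(row[f"{col}_ic50_uM"]):
                ic50 = float(row[f"{col}_ic50_uM"]) * 1000.0
                log.info("drug %s: converted %s IC50 from uM to nM", name, cur)
            hill = 1.0
            if f"{col}_hill" in df.columns and not pd.isna(row.get(f"{col}_hill")):
                hill = float(row[f"{col}_hill"])
            if math.isfinite(ic50):
                if ic50 <= 0:
                    raise SchemaError(
                        f"{path}: drug {name!r} nonpositive IC50 in {col}_ic50")
                blocks[cur] = ChannelBlock(cur, ic50, hill)

        label = None
        if "risk_label" in df.columns and not pd.isna(row.get("risk_label")):
            label = str(row["risk_label"])
            if label not in RISK_CATEGORIES:
                raise SchemaError(f"{path}: drug {name!r} bad risk_label {label!r}")
        records.append(DrugRecord(name, cmax, herg, blocks, label))
    return records


def write_drug_table(records: list[DrugRecord], path) -> None:
    rows = []
    for r in records:
        row = {"drug": r.name, "cmax_nM": r.cmax_nM, "risk_label": r.risk_label,
               "herg_kmax": r.herg.kmax, "herg_ku": r.herg.ku,
               "herg_n": r.herg.n, "herg_halfmax": r.herg.halfmax,
               "herg_vhalf": r.herg.vhalf}
        for col, cur in _CURRENT_COLS.items():
            blk = r.blocks.get(cur)
            if blk is not None and math.isfinite(blk.ic50_nM):
                row[f"{col}_ic50_nM"] = blk.ic50_nM
                row[f"{col}_hill"] = blk.hill
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_cell_responses(path) -> list[CellResponse]:
    df = pd.read_csv(path)
    required = {"drug", "current", "cell_id", "conc_nM", "frac_block"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing column(s) {sorted(missing)}")
    return [
        CellResponse(drug=str(r.drug), cell_id=str(r.cell_id),
                     concentration_nM=float(r.conc_nM),
                     fractional_block=float(r.frac_block),
                     current_id=str(r.current))
        for r in df.itertuples()
    ]


def write_cell_responses(responses: list[CellResponse], path) -> None:
    pd.DataFrame([
        {"drug": r.drug, "current": r.current_id, "cell_id": r.cell_id,
         "conc_nM": r.concentration_nM, "frac_block": r.fractional_block}
        for r in responses
    ]).to_csv(path, index=False)


def write_sample_set(ss: DrugSampleSet, path) -> None:
    """One CSV per drug, one row per bootstrap replicate."""
    rows = []
    for i, (herg, blocks) in enumerate(ss.samples):
        row = {"sample_index": i, "herg_kmax": herg.kmax, "herg_ku": herg.ku,
               "herg_n": herg.n, "herg_halfmax": herg.halfmax,
               "herg_vhalf": herg.vhalf}
        for col, cur in _CURRENT_COLS.items():
            blk = blocks.get(cur)
            if blk is not None and math.isfinite(blk.ic50_nM):
                row[f"{col}_ic50_nM"] = blk.ic50_nM
                row[f"{col}_hill"] = blk.hill
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_sample_set(path, drug: str) -> DrugSampleSet:
    df = pd.read_csv(path)
    samples = []
    for _, row in df.iterrows():
        herg = HergDynamicParams(
            kmax=float(row["herg_kmax"]), ku=float(row["herg_ku"]),
            n=float(row["herg_n"]), halfmax=float(row["herg_halfmax"]),
            vhalf=float(row["herg_vhalf"]),
        )
        blocks = {}
        for col, cur in _CURRENT_COLS.items():
            key = f"{col}_ic50_nM"
            if key in df.columns and not pd.isna(row[key]):
                blocks[cur] = ChannelBlock(cur, float(row[key]),
                                           float(row.get(f"{col}_hill", 1.0)))
        samples.append((herg, blocks))
    return DrugSampleSet(drug, samples)


def write_score_table(dists: list[ScoreDistribution], path,
                      n_failures: dict[str, int] | None = None) -> None:
    rows = []
    for d in dists:
        for i, s in enumerate(d.scores):
            rows.append({"drug": d.drug, "sample_index": i,
                         "score_uC_per_uF": s, "risk_label": d.risk_label,
                         "n_failed_samples": (n_failures or {}).get(d.drug, 0)})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_score_table(path) -> list[ScoreDistribution]:
    df = pd.read_csv(path)
    out = []
    for drug, grp in df.groupby("drug", sort=False):
        label = grp["risk_label"].iloc[0]
        label = None if pd.isna(label) else str(label)
        out.append(ScoreDistribution(str(drug),
                                     grp["score_uC_per_uF"].to_numpy(float),
                                     label))
    return out


def write_thresholds(th: Thresholds, path, dataset_id: str = "",
                     diagnostics: dict | None = None) -> None:
    payload = {"dataset_id": dataset_id, "t1": th.t1, "t2": th.t2,
               "diagnostics": diagnostics or {}}
    Path(path).write_text(json.dumps(payload, indent=2))


def read_thresholds(path) -> Thresholds:
    payload = json.loads(Path(path).read_text())
    return Thresholds(t1=float(payload["t1"]), t2=float(payload["t2"]))


def write_report(report, path, extra_meta: dict | None = None) -> None:
    payload = report.to_dict()
    payload["meta"].update(extra_meta or {})
    Path(path).write_text(json.dumps(payload, indent=2, default=str))


@dataclass
class RunConfig:
    """End-to-end pipeline configuration (YAML-loadable)."""

    model_id: str = "toy"
    dataset_id: str = "synthetic"
    cycle_length_ms: float = 2000.0
    n_beats: int = 1000
    stimulus_amplitude: float = -80.0
    stimulus_duration_ms: float = 0.5
    multiples: tuple = (1.0, 2.0, 3.0, 4.0)
    n_uq_samples: int = 2000
    n_eval_iters: int = 10_000
    seed: int = 0
    training_table: str | None = None
    validation_table: str | None = None
    training_responses: str | None = None
    validation_responses: str | None = None
    output_dir: str = "cipasim_out"

    def __post_init__(self):
        if self.n_uq_samples < 1 or self.n_eval_iters < 1:
            raise SchemaError("sample/iteration counts must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise SchemaError(f"{path}: unknown config key(s) {sorted(unknown)}")
        if "multiples" in data:
            data["multiples"] = tuple(data["multiples"])
        return cls(**data)

    def sha256(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]
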