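"""File formats and run configuration.

All interchange is comma-separated UTF-8 with "." decimals. Trial data
travel as participant-level CSV (id, arm, y1, y2; empty cell or NA =
missing); expert questionnaire responses as one CSV row per expert;
multiple imputations as long-format CSV; every run can write a manifest
(config + seed + version) sufficient to reproduce its outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .elicitation import ExpertResponse
from .impute import ImputationConfig, MultipleImputations, SPSet
from .sensitivity import SAResult, SPGridConfig
from .synthetic import TrialDataset, TrialTruth

__all__ = [
    "read_trial_csv",
    "write_trial_csv",
    "write_truth_csv",
    "read_expert_responses",
    "write_expert_responses",
    "write_imputations_csv",
    "read_imputations_csv",
    "write_sa_csv",
    "read_sa_csv",
    "RunConfig",
    "write_manifest",
]

_ARM_CODES = {"0": 0, "control": 0, "c": 0, "1": 1, "intervention": 1,
              "experimental": 1, "e": 1}
_MISSING_TOKENS = {"", "na", "nan", "none", "null", "."}

RESPONSE_COLUMNS = ["expert_id", "mode_1C", "cert_1C", "mode_1E", "cert_1E",
                    "mode_2C", "cert_2C", "mode_2E", "cert_2E", "updated_mode_1C"]


def read_trial_csv(path) -> TrialDataset:
    """Parse participant-level trial CSV with strict validation.

    Empty cells and NA tokens are missing outcomes; arm accepts 0/1 or the
    words control/intervention/experimental. Unknown codes, duplicate ids
    and non-binary outcomes are reported with their row numbers.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = ["id", "arm", "y1", "y2"]
    lacking = [c for c in required if c not in raw.columns]
    if lacking:
        raise ValueError(f"{path}: missing required columns {lacking}")

    def parse_arm(val: str, row: int) -> int:
        key = val.strip().lower()
        if key not in _ARM_CODES:
            raise ValueError(f"{path} row {row + 2}: unknown arm code {val!r}")
        return _ARM_CODES[key]

    def parse_y(val: str, row: int, col: str) -> float:
        key = val.strip().lower()
        if key in _MISSING_TOKENS:
            return np.nan
        if key in ("0", "0.0"):
            return 0.0
        if key in ("1", "1.0"):
            return 1.0
        raise ValueError(f"{path} row {row + 2}: non-binary value {val!r} in {col}")

    frame = pd.DataFrame({
        "id": raw["id"].to_numpy(),
        "arm": [parse_arm(v, i) for i, v in enumerate(raw["arm"])],
        "y1": [parse_y(v, i, "y1") for i, v in enumerate(raw["y1"])],
        "y2": [parse_y(v, i, "y2") for i, v in enumerate(raw["y2"])],
    })
    dup = frame["id"].duplicated()
    if dup.any():
        rows = [i + 2 for i in np.flatnonzero(dup)]
        raise ValueError(f"{path}: duplicate ids at rows {rows[:10]}")
    return TrialDataset(frame)


def write_trial_csv(data: TrialDataset, path) -> None:
    out = data.frame.copy()
    for c in ("y1", "y2"):
        out[c] = out[c].map(lambda v: "" if pd.isna(v) else str(int(v)))
    out.to_csv(path, index=False)


def write_truth_csv(truth: TrialTruth, path) -> None:
    """Sidecar CSV of the pre-mask outcomes, mask, and true pi^NR values."""
    out = truth.complete.frame.copy()
    out["m1"] = truth.mask["m1"].to_numpy()
    out["m2"] = truth.mask["m2"].to_numpy()
    out.to_csv(path, index=False)
    meta = {f"pi_{t}{'C' if z == 0 else 'E'}": truth.true_pi_nr[(z, t)]
            for (z, t) in sorted(truth.true_pi_nr)}
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=2))


# ---------------------------------------------------------------------------
# Expert responses
# ---------------------------------------------------------------------------

def read_expert_responses(path) -> list[ExpertResponse]:
    """Read questionnaire responses from CSV (or a JSON list of objects)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        records = json.loads(path.read_text())
    else:
        frame = pd.read_csv(path)
        lacking = [c for c in RESPONSE_COLUMNS if c not in frame.columns]
        if lacking:
            raise ValueError(f"{path}: missing required column(s) {lacking}")
        records = frame.to_dict("records")
    if not records:
        import warnings

        warnings.warn(f"{path}: no expert responses found")
        return []
    out = []
    for rec in records:
        out.append(ExpertResponse(
            expert_id=str(rec["expert_id"]),
            modes={k: float(rec[f"mode_{k}"]) for k in ExpertResponse.KEYS},
            certainties={k: float(rec[f"cert_{k}"]) for k in ExpertResponse.KEYS},
            updated_mode_1C=float(rec["updated_mode_1C"]),
            rationale=str(rec.get("rationale", "") or ""),
        ))
    return out


def write_expert_responses(responses: list[ExpertResponse], path) -> None:
    rows = []
    for r in responses:
        row = {"expert_id": r.expert_id}
        for k in ExpertResponse.KEYS:
            row[f"mode_{k}"] = r.modes[k]
            row[f"cert_{k}"] = r.certainties[k]
        row["updated_mode_1C"] = r.updated_mode_1C
        row["rationale"] = r.rationale
        rows.append(row)
    pd.DataFrame(rows, columns=RESPONSE_COLUMNS + ["rationale"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Imputations and SA results
# ---------------------------------------------------------------------------

def write_imputations_csv(imps: MultipleImputations, path) -> None:
    """Long format: one row per (imputation, participant)."""
    parts = []
    for i, d in enumerate(imps.datasets, start=1):
        block = d.frame.copy()
        block.insert(0, "imputation", i)
        parts.append(block)
    pd.concat(parts).to_csv(path, index=False)


def read_imputations_csv(path, original: TrialDataset,
                         config: ImputationConfig | None = None,
                         sp: SPSet | None = None) -> MultipleImputations:
    frame = pd.read_csv(path)
    datasets = [TrialDataset(g.drop(columns="imputation"))
                for _, g in frame.groupby("imputation", sort=True)]
    return MultipleImputations(datasets=datasets, original=original,
                               sp=sp, config=config or ImputationConfig(m=len(datasets)))


def write_sa_csv(res: SAResult, path) -> None:
    res.table.to_csv(path, index=False)


def read_sa_csv(path) -> SAResult:
    return SAResult(table=pd.read_csv(path, keep_default_na=True,
                                      dtype={"error": str}).fillna({"error": ""}))


# ---------------------------------------------------------------------------
# Run configuration and manifests
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Paths plus stage settings for a full pipeline run."""

    trial_csv: str = ""
    responses_csv: str = ""
    out_dir: str = "."
    seed: int = 0
    imputation: ImputationConfig = field(default_factory=ImputationConfig)
    grid: SPGridConfig = field(default_factory=SPGridConfig)
    n_per_expert: int = 100_000
    coverages: tuple = (0.5, 0.9)
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        raw = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
        raw = dict(raw or {})
        imp = ImputationConfig(**raw.pop("imputation", {}))
        grid_raw = raw.pop("grid", {})
        if "delta_range" in grid_raw:
            grid_raw["delta_range"] = tuple(grid_raw["delta_range"])
        if "linkage_constants" in grid_raw:
            grid_raw["linkage_constants"] = tuple(grid_raw["linkage_constants"])
        grid = SPGridConfig(**grid_raw)
        if "coverages" in raw:
            raw["coverages"] = tuple(raw["coverages"])
        return cls(imputation=imp, grid=grid, **raw)

    def to_dict(self) -> dict:
        return {
            "trial_csv": self.trial_csv, "responses_csv": self.responses_csv,
            "out_dir": self.out_dir, "seed": self.seed,
            "imputation": {"m": self.imputation.m, "n_cycles": self.imputation.n_cycles,
                           "seed": self.imputation.seed, "ridge": self.imputation.ridge},
            "grid": {"delta_range": list(self.grid.delta_range), "step": self.grid.step,
                     "linkage_constants": list(self.grid.linkage_constants)},
            "n_per_expert": self.n_per_expert, "coverages": list(self.coverages),
            "log_level": self.log_level,
        }


def write_manifest(out_dir, command: str, settings: dict, seed: int) -> Path:
    """Record everything needed to reproduce a run."""
    path = Path(out_dir) / f"manifest_{command}.json"
    path.write_text(json.dumps({
        "command": command,
        "package_version": __version__,
        "seed": seed,
        "settings": settings,
    }, indent=2, default=str))
    return path
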