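"""Tabular input/output: long-format group tables and run reports."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .kde import OverlapMatrix, PairOverlap, Sample
from .resampling import BootstrapResult

__all__ = ["RunConfig", "read_groups", "samples_to_frame", "write_long_csv", "write_report"]

log = logging.getLogger("distoverlap")

REPORT_PRECISION = 6


@dataclass(frozen=True)
class RunConfig:
    """Configuration echoed into every report for reproducibility."""

    input: str = ""
    value_column: str = "value"
    group_column: str = "group"
    nbins: int = 1024
    kernel: str = "gaussian"
    bandwidth: str | float = "silverman_nrd0"
    boot_B: int | None = None
    level: float = 0.95
    seed: int = 0
    output_format: str = "json"

    def __post_init__(self) -> None:
        if self.nbins < 16:
            raise ValueError("nbins must be >= 16")
        if not (0.0 < self.level < 1.0):
            raise ValueError("level must be in (0, 1)")
        if self.output_format not in ("json", "tsv"):
            raise ValueError("output format must be 'json' or 'tsv'")


def read_groups(
    path: str | Path, value_column: str = "value", group_column: str = "group"
) -> list[Sample]:
    """Read a long-format CSV/TSV into one :class:`Sample` per group.

    Missing or non-numeric value cells are dropped per group with a logged
    count; groups appear in order of first appearance in the file.  At
    least two groups with >= 3 clean observations each are required.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    for col in (value_column, group_column):
        if col not in df.columns:
            raise ValueError(f"column {col!r} not found in {path} (columns: {list(df.columns)})")

    values = pd.to_numeric(df[value_column], errors="coerce")
    groups = df[group_column].astype(str)
    samples: list[Sample] = []
    for label in groups[~groups.isna()].unique():
        mask = groups == label
        clean = values[mask].dropna().to_numpy(dtype=float)
        clean = clean[np.isfinite(clean)]
        dropped = int(mask.sum()) - clean.size
        if dropped:
            log.info("group %r: dropped %d missing/non-numeric rows", label, dropped)
        if clean.size < 3:
            raise ValueError(
                f"group {label!r} has only {clean.size} usable observations (need >= 3)"
            )
        samples.append(Sample(label, clean))
    if len(samples) < 2:
        raise ValueError(f"need at least 2 groups, found {len(samples)} in {path}")
    return samples


def samples_to_frame(samples: list[Sample]) -> pd.DataFrame:
    """Stack samples into the long (value, group) format read_groups consumes."""
    return pd.DataFrame(
        {
            "value": np.concatenate([s.values for s in samples]),
            "group": np.concatenate([[s.label] * s.n for s in samples]),
        }
    )


def write_long_csv(samples: list[Sample], path: str | Path) -> None:
    samples_to_frame(samples).to_csv(path, index=False)


def _round(x: float) -> float:
    return round(float(x), REPORT_PRECISION)


def _pair_record(
    p: PairOverlap, boot: BootstrapResult | None = None
) -> dict:
    rec = {
        "group_a": p.label_a,
        "group_b": p.label_b,
        "eta": _round(p.eta),
        "delta": _round(1.0 - p.eta),
        "xpoints": [_round(x) for x in np.asarray(p.xpoints)],
        "bandwidth_a": _round(p.bandwidth_a),
        "bandwidth_b": _round(p.bandwidth_b),
        "grid": {
            "lower": _round(p.grid.lower),
            "upper": _round(p.grid.upper),
            "nbins": p.grid.nbins,
        },
    }
    if boot is not None:
        rec["bootstrap"] = {
            "B": int(boot.replicates.size),
            "level": boot.level,
            "lower": _round(boot.lower),
            "upper": _round(boot.upper),
        }
    return rec


def write_report(
    matrix: OverlapMatrix,
    pairs: list[PairOverlap],
    boot: dict[tuple[str, str], BootstrapResult] | None,
    config: RunConfig,
    path: str | Path,
) -> None:
    """Write the run report as JSON (schema below) or a one-row-per-pair TSV.

    JSON schema: ``{"version", "config", "labels", "matrix", "pairs": [...]}``
    with per-pair eta/delta at 6 decimals, intersection abscissas,
    bandwidths, grid bounds and optional bootstrap interval.
    """
    boot = boot or {}
    records = [_pair_record(p, boot.get((p.label_a, p.label_b))) for p in pairs]
    path = Path(path)
    if config.output_format == "tsv":
        rows = []
        for rec in records:
            row = {
                "group_a": rec["group_a"],
                "group_b": rec["group_b"],
                "eta": rec["eta"],
                "delta": rec["delta"],
                "xpoints": ";".join(str(x) for x in rec["xpoints"]),
                "bandwidth_a": rec["bandwidth_a"],
                "bandwidth_b": rec["bandwidth_b"],
            }
            if "bootstrap" in rec:
                row["boot_lower"] = rec["bootstrap"]["lower"]
                row["boot_upper"] = rec["bootstrap"]["upper"]
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        return

    report = {
        "version": __version__,
        "config": asdict(config),
        "labels": list(matrix.labels),
        "matrix": [[_round(v) for v in row] for row in matrix.values],
        "pairs": records,
    }
    path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


def read_report(path: str | Path) -> dict:
    """Re-read a JSON report written by :func:`write_report`."""
    return json.loads(Path(path).read_text())
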