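"""Plain-text file formats: TSV panels, labels, scores, networks; YAML config.

All serialized node indices are 0-based; region labels travel alongside for
reporting.  Formats round-trip losslessly within float formatting precision
(17 significant digits are written).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .behavior import CognitiveScoreTable
from .connectivity import NetworkAssignment
from .decoding import Partition
from .errors import ParseError
from .panel import TimeSeriesPanel

__all__ = [
    "RunConfig",
    "read_panel", "write_panel",
    "read_labels", "write_labels",
    "read_scores", "write_scores",
    "read_network", "write_network",
    "write_diagrams",
]


@dataclass
class RunConfig:
    """Parameters of a pipeline run; round-trips through YAML unchanged."""

    panels_dir: str = "panels"
    labels_path: str = "labels.tsv"
    network_path: str = "networks.tsv"
    scores_path: str = "scores.tsv"
    out_dir: str = "out"
    k_max: int = 2
    percentile_q: float = 95.0
    louvain_seed: int = 0
    louvain_restarts: int = 10
    ecs_alpha: float = 0.9
    n_slices: int = 50
    n_perm: int = 1000
    n_boot: int = 1000
    n_sub: int = 80
    n_rep: int = 100
    seed: int = 0
    cohort: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 1 <= self.k_max <= 3:
            raise ValueError("k_max must be 1..3")
        if not 0 < self.percentile_q < 100:
            raise ValueError("percentile_q must be in (0, 100)")
        if not 0 < self.ecs_alpha <= 1:
            raise ValueError("ecs_alpha must be in (0, 1]")
        for name in ("louvain_restarts", "n_slices", "n_perm", "n_boot",
                     "n_sub", "n_rep"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ParseError(f"{path}: expected a mapping at top level")
        return cls(**data)


def _read_lines(path: str | Path) -> list[str]:
    text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ParseError(f"{path}: empty input file")
    return lines


def read_panel(path: str | Path) -> TimeSeriesPanel:
    """TSV with a leading region-label column, one row per region."""
    lines = _read_lines(path)
    labels: list[str] = []
    rows: list[list[float]] = []
    width = None
    for ln_no, ln in enumerate(lines, start=1):
        cells = ln.split("\t")
        if len(cells) < 2:
            raise ParseError(f"{path}:{ln_no}: need a label and at least one value")
        if width is None:
            width = len(cells)
        elif len(cells) != width:
            raise ParseError(f"{path}:{ln_no}: ragged row "
                             f"({len(cells)} cells, expected {width})")
        labels.append(cells[0])
        try:
            rows.append([float(c) for c in cells[1:]])
        except ValueError as exc:
            raise ParseError(f"{path}:{ln_no}: non-numeric cell ({exc})") from exc
    if len(set(labels)) != len(labels):
        raise ParseError(f"{path}: duplicate region labels")
    return TimeSeriesPanel(np.asarray(rows), labels)


def write_panel(panel: TimeSeriesPanel, path: str | Path) -> None:
    with open(path, "w") as fh:
        for label, row in zip(panel.region_labels, panel.values):
            fh.write(label + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_labels(path: str | Path) -> Partition:
    """Two-column TSV (frame, state), frames in order."""
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != ["frame", "state"]:
        raise ParseError(f"{path}: expected columns 'frame' and 'state'")
    df = df.sort_values("frame")
    if not np.array_equal(df["frame"].to_numpy(), np.arange(len(df))):
        raise ParseError(f"{path}: frames must be 0..T-1 without gaps")
    return Partition(df["state"].to_numpy())


def write_labels(partition: Partition, path: str | Path) -> None:
    pd.DataFrame({"frame": np.arange(partition.n_elements),
                  "state": partition.labels}).to_csv(path, sep="\t", index=False)


def read_scores(path: str | Path) -> CognitiveScoreTable:
    """TSV: subject column then one column per score."""
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "subject":
        raise ParseError(f"{path}: first column must be 'subject'")
    return CognitiveScoreTable(df.iloc[:, 1:].to_numpy(dtype=float),
                               [str(c) for c in df.columns[1:]])


def write_scores(table: CognitiveScoreTable, path: str | Path,
                 subjects: list[str] | None = None) -> None:
    subjects = subjects or [f"sub{i:03d}" for i in range(table.values.shape[0])]
    df = pd.DataFrame(table.values, columns=table.subdomains)
    df.insert(0, "subject", subjects)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_network(path: str | Path) -> NetworkAssignment:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != ["region", "network"]:
        raise ParseError(f"{path}: expected columns 'region' and 'network'")
    df = df.sort_values("region")
    return NetworkAssignment([str(x) for x in df["network"]])


def write_network(assignment: NetworkAssignment, path: str | Path) -> None:
    assignment.to_frame().to_csv(path, sep="\t", index=False)


def write_diagrams(diagrams, path: str | Path) -> None:
    """Persistence diagrams for a scan as JSON, one record per frame."""
    out = []
    for t, d in enumerate(diagrams):
        out.append({
            "frame": t,
            "bars": [
                {"birth": float(b), "death": float(dd), "essential": bool(e),
                 "generator": [list(edge) for edge in g]}
                for b, dd, e, g in zip(d.births, d.deaths, d.essential, d.generators)
            ],
        })
    Path(path).write_text(json.dumps(out))
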