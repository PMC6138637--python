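"""Pipeline orchestration, configuration and serialization.

Runs the four-group analysis end to end — load or simulate SUVR tables,
correlate, sweep/select the threshold, binarize, partition, and run the
group-pair t-tests — and writes a reproducible output bundle: correlation
matrices, edge lists, BrainNet Viewer ``.node``/``.edge`` files, comparison
tables, summary tables, and a manifest with checksums of everything
produced. Identical config + seed reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .atlas import RegionAtlas, load_atlas
from .network import (
    BinaryNetwork,
    ConnectivityReport,
    CorrMatrix,
    connectivity_report,
    default_grid,
)
from .simulate import make_default_cohort
from .suvr import SuvrDataset, group_ttest, load_suvr_table

__all__ = [
    "RunConfig",
    "RunManifest",
    "PipelineError",
    "run_pipeline",
    "write_summary_tables",
    "write_matrix",
    "read_matrix",
    "write_edge_list",
    "write_brainnet",
    "parse_grid_spec",
]

log = logging.getLogger("metaconn")

GROUP_PAIRS = [("NC", "AD"), ("pMCI", "AD"), ("NC", "sMCI"), ("sMCI", "pMCI")]

# 17 significant digits round-trips IEEE doubles exactly
_FLOAT_FMT = "%.17g"


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and input."""


def parse_grid_spec(spec: str) -> np.ndarray:
    """Parse "start:stop:step" (inclusive endpoints) into a threshold grid."""
    try:
        start, stop, step = (float(x) for x in spec.split(":"))
    except ValueError:
        raise ValueError(f"grid spec must be start:stop:step, got {spec!r}") from None
    n = int(round((stop - start) / step)) + 1
    grid = np.round(start + step * np.arange(n), 10)
    return grid[grid <= stop + 1e-9]


@dataclass
class RunConfig:
    """Everything a pipeline run depends on.

    Exactly one input mode: either ``group_files`` maps each of the four
    group labels to a table path, or ``synthetic`` is true and the default
    simulated cohort is generated from ``seed``.
    """

    out_dir: str | Path
    synthetic: bool = False
    seed: int = 0
    group_files: dict[str, str] = field(default_factory=dict)
    atlas_path: str | None = None
    grid_spec: str = "0.5:0.9:0.02"
    tau: float | None = None  # None = auto-select from NC
    selection_rule: str = "largest"
    alpha: float = 0.01
    ttest_variant: str = "pooled"
    correction: str = "none"

    def __post_init__(self):
        if self.synthetic == bool(self.group_files):
            raise ValueError("config must set exactly one of synthetic/group_files")
        grid = parse_grid_spec(self.grid_spec)
        if grid.size == 0 or np.any(np.diff(grid) <= 0):
            raise ValueError(f"grid spec {self.grid_spec!r} is not increasing")
        if grid[0] <= 0 or grid[-1] >= 1:
            raise ValueError(f"grid spec {self.grid_spec!r} leaves (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["out_dir"] = str(d["out_dir"])
        return d


@dataclass
class RunManifest:
    config: dict
    version: str
    seed: int
    selected_tau: float
    tau_mode: str
    group_sizes: dict[str, int]
    edge_counts: dict[str, int]
    node_counts: dict[str, int]
    files: dict[str, str]  # relative path -> sha256
    timestamp: str = ""

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_matrix(corr: CorrMatrix, path: Path) -> None:
    """Write a correlation matrix as delimited text with region-name headers."""
    corr.to_frame().to_csv(path, float_format=_FLOAT_FMT)


def read_matrix(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0, float_precision="round_trip")


def write_edge_list(net: BinaryNetwork, corr: CorrMatrix, path: Path) -> None:
    """Three-column edge list (region_a, region_b, r)."""
    pos_r = {n: i for i, n in enumerate(corr.row_regions)}
    pos_c = {n: i for i, n in enumerate(corr.col_regions)}
    rows = [
        {"region_a": a, "region_b": b, "r": corr.values[pos_r[a], pos_c[b]]}
        for a, b in net.edge_list
    ]
    pd.DataFrame(rows, columns=["region_a", "region_b", "r"]).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


_LOBE_COLOR_CODE = {
    "FRONTAL": 1,
    "TEMPORAL": 2,
    "PARIETAL": 3,
    "OCCIPITAL": 4,
    "SUBCORTICAL": 5,
    "HIPPOCAMPUS": 6,
    "OTHER": 7,
}


def write_brainnet(
    net: BinaryNetwork, atlas: RegionAtlas, node_path: Path, edge_path: Path
) -> None:
    """Write BrainNet Viewer ``.node`` and ``.edge`` plain-text files.

    ``.node``: one region per line — x y z color size label, with color
    coded by lobe category and size by degree. ``.edge``: the full N x N
    binary adjacency, whitespace-delimited.
    """
    if net.kind != "FULL":
        raise ValueError("BrainNet export expects a FULL network")
    degree = net.adjacency.sum(axis=0)
    lines = []
    for k, name in enumerate(net.row_regions):
        reg = atlas[name]
        x, y, z = reg.centroid
        color = _LOBE_COLOR_CODE[reg.lobe.value]
        size = max(int(degree[k]), 1)
        lines.append(f"{x:g}\t{y:g}\t{z:g}\t{color}\t{size}\t{name}")
    node_path.write_text("\n".join(lines) + "\n")
    np.savetxt(edge_path, net.adjacency, fmt="%d", delimiter="\t")


def _load_cohort(config: RunConfig, atlas: RegionAtlas) -> dict[str, SuvrDataset]:
    if config.synthetic:
        log.info("simulating default cohort (seed=%d)", config.seed)
        return make_default_cohort(config.seed)
    cohort = {}
    for label, path in config.group_files.items():
        try:
            cohort[label] = load_suvr_table(path, atlas, group_label=label)
        except Exception as exc:
            raise PipelineError(f"load_suvr_table failed for {path}: {exc}") from exc
        log.info(
            "loaded group %s: %d subjects x %d regions",
            label,
            cohort[label].n_subjects,
            len(cohort[label].region_names),
        )
    return cohort


def write_summary_tables(report: ConnectivityReport, out_dir: str | Path) -> list[Path]:
    """Write per-group counts, lobe-pair counts, and lobe-pair ratio tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, frame, kw in (
        ("summary_groups.csv", report.summary_frame(), dict(index=False)),
        ("lobe_pair_counts.csv", report.lobe_pair_frame(), dict(index=False)),
        ("lobe_pair_ratios.csv", report.lobe_pair_ratios(), dict(index=True)),
    ):
        p = out / name
        # NaN marks an undefined ratio (zero denominator), never infinity
        frame.to_csv(p, na_rep="undefined", **kw)
        paths.append(p)
    return paths


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the full analysis described by ``config``; returns the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    atlas = load_atlas(config.atlas_path)
    grid = parse_grid_spec(config.grid_spec)

    cohort = _load_cohort(config, atlas)
    try:
        report = connectivity_report(
            cohort,
            atlas,
            grid=grid,
            tau=config.tau,
            selection_rule=config.selection_rule,
        )
    except Exception as exc:
        raise PipelineError(f"connectivity_report failed: {exc}") from exc
    log.info("selected tau=%.2f (%s)", report.threshold, report.tau_mode)

    written: list[Path] = []
    for g in report.group_order:
        write_matrix(report.full_matrices[g], out / f"corr_full_{g}.csv")
        write_matrix(report.interhemi_matrices[g], out / f"corr_interhemi_{g}.csv")
        write_edge_list(
            report.networks[g], report.full_matrices[g], out / f"edges_{g}.csv"
        )
        write_brainnet(
            report.networks[g], atlas, out / f"brainnet_{g}.node",
            out / f"brainnet_{g}.edge",
        )
        written += [
            out / f"corr_full_{g}.csv",
            out / f"corr_interhemi_{g}.csv",
            out / f"edges_{g}.csv",
            out / f"brainnet_{g}.node",
            out / f"brainnet_{g}.edge",
        ]
    written += write_summary_tables(report, out)

    for ga, gb in GROUP_PAIRS:
        if ga not in cohort or gb not in cohort:
            continue
        try:
            res = group_ttest(
                cohort[ga],
                cohort[gb],
                alpha=config.alpha,
                variant=config.ttest_variant,
                correction=config.correction,
            )
        except Exception as exc:
            raise PipelineError(f"group_ttest failed for {ga} vs {gb}: {exc}") from exc
        p = out / f"ttest_{ga}_vs_{gb}.csv"
        res.to_frame().to_csv(p, index=False, float_format=_FLOAT_FMT)
        written.append(p)
        log.info(
            "t-test %s vs %s: %d/%d significant at alpha=%g",
            ga, gb, len(res.significant_regions), len(res.regions), config.alpha,
        )

    summary = report.summary_frame().set_index("group")
    manifest = RunManifest(
        config=config.to_dict(),
        version=__version__,
        seed=config.seed,
        selected_tau=report.threshold,
        tau_mode=report.tau_mode,
        group_sizes={g: int(summary.loc[g, "n_subjects"]) for g in report.group_order},
        edge_counts={g: int(summary.loc[g, "total_edges"]) for g in report.group_order},
        node_counts={g: int(summary.loc[g, "nodes"]) for g in report.group_order},
        files={str(p.relative_to(out)): _sha256(p) for p in written},
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    manifest.write(out / "manifest.json")
    return manifest
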