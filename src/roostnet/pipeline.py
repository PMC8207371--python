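"""End-to-end orchestration: simulate/read -> networks -> metrics -> QAP.

One run partitions the windowed detections by roost-day year (network
composition changes between years through births, deaths, dispersal and
newly tagged animals, so years are never pooled), and for each year
writes: both weighted matrices (square CSV + edge list), their
dichotomized versions, a summary table of the four network statistics
(rounded to report precision, with a full-precision companion), the QAP
comparison as JSON, aligned heat-map matrices sharing one node order
with the diagonal masked, and a machine-readable run log with event and
skip counts. Given the same inputs, config and seed, every output byte
is identical across runs.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
import logging
import shutil
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io import (
    AntennaRegistry,
    DetectionEvent,
    StudyWindow,
    events_frame,
    filter_window,
    read_detections,
)
from .metrics import centralization, degree_centrality, density, diameter
from .networks import (
    AssociationMatrix,
    align_matrices,
    bin_detections,
    build_cohabitation,
    build_intraroost,
    daily_presence,
    dichotomize,
)
from .qap import qap_test
from .simulate import ColonyConfig, antenna_registry_for, simulate_colony

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """One pipeline run: exactly one of (detections_path, colony) as input."""

    output_dir: str | Path
    detections_path: str | Path | None = None
    antennas_path: str | Path | None = None
    colony: ColonyConfig | None = None
    window: StudyWindow | None = None
    alignment: str = "union"
    threshold: int = 1
    n_permutations: int = 10_000
    seed: int = 0
    site_label: str = "colony"
    heatmap_image: bool = False

    def __post_init__(self) -> None:
        if (self.detections_path is None) == (self.colony is None):
            raise ValueError("provide exactly one of detections_path or colony")
        if self.detections_path is not None and self.antennas_path is None:
            raise ValueError("a detection log requires an antenna registry")
        if self.alignment not in ("union", "intersection"):
            raise ValueError("alignment must be 'union' or 'intersection'")


def export_heatmap(
    a: AssociationMatrix,
    b: AssociationMatrix,
    path_prefix: str | Path,
    image: bool = False,
) -> tuple[Path, Path]:
    """Write the aligned weighted matrices as a comparable heat-map pair.

    Both CSVs use the identical node order and leave the diagonal cells
    empty (a bat's association with itself is meaningless). With
    ``image=True`` a side-by-side raster rendering is also written.
    """
    if a.nodes != b.nodes:
        raise ValueError("heat-map export requires aligned matrices")
    prefix = Path(path_prefix)
    paths = []
    for m, tag in ((a, a.kind), (b, b.kind)):
        df = m.to_frame().astype(object)
        for i in range(m.n_nodes):
            df.iat[i, i] = ""
        p = prefix.parent / f"{prefix.name}_{tag}.csv"
        df.to_csv(p, index_label="tag_id")
        paths.append(p)
    if image:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, 2, figsize=(11, 5))
        for ax, m in zip(axes, (a, b)):
            w = m.weights.astype(float)
            np.fill_diagonal(w, np.nan)
            im = ax.imshow(w, cmap="inferno")
            ax.set_title(m.kind)
            fig.colorbar(im, ax=ax, shrink=0.8)
        fig.suptitle("Dyadic association strength (same bats, same order)")
        fig.savefig(prefix.parent / f"{prefix.name}.png", dpi=120)
        plt.close(fig)
    return paths[0], paths[1]


def _year_of(day) -> int:
    return day.year if hasattr(day, "year") else dt.date.fromisoformat(str(day)).year


def _analyze_year(
    year_dir: Path,
    year: int,
    presence: pd.DataFrame,
    bins: pd.DataFrame,
    cfg: RunConfig,
) -> tuple[list[dict], dict]:
    """Build, measure, compare, and write one year's pair of networks."""
    year_dir.mkdir(parents=True, exist_ok=True)
    matrices: dict[str, AssociationMatrix] = {}
    if not presence.empty:
        matrices["cohabitation"] = build_cohabitation(presence)
    if not bins.empty:
        matrices["intraroost"] = build_intraroost(bins)
    if not matrices:
        raise ValueError(f"year {year}: no entry or ceiling detections in window")

    summary_rows: list[dict] = []
    for kind, mat in matrices.items():
        mat.to_csv(year_dir / f"{kind}.csv")
        mat.to_edge_list().to_csv(year_dir / f"{kind}_edges.csv", index=False)
        binary = dichotomize(mat, cfg.threshold)
        binary.to_csv(year_dir / f"{kind}_binary.csv")
        row: dict = {"roost": cfg.site_label, "network": kind, "year": year,
                     "nodes": binary.n_nodes}
        # tiny or tieless networks leave some statistics undefined; report
        # NaN and keep going rather than abort the whole year
        for name, fn in (
            ("density", density),
            ("diameter", diameter),
            ("centralization", centralization),
            ("avg_degree_centrality", lambda m: degree_centrality(m)[1]),
        ):
            try:
                row[name] = fn(binary)
            except ValueError as exc:
                logger.warning("year %d %s: %s undefined (%s)", year, kind, name, exc)
                row[name] = float("nan")
        summary_rows.append(row)

    qap_info: dict = {}
    if len(matrices) == 2:
        coh, intra = matrices["cohabitation"], matrices["intraroost"]
        a_w, b_w = align_matrices(coh, intra, cfg.alignment)
        export_heatmap(a_w, b_w, year_dir / "heatmap", image=cfg.heatmap_image)
        a_bin = dichotomize(a_w, cfg.threshold)
        b_bin = dichotomize(b_w, cfg.threshold)
        result = qap_test(
            a_bin, b_bin, n_permutations=cfg.n_permutations, seed=cfg.seed
        )
        result.to_json(year_dir / "qap.json")
        qap_info = dataclasses.asdict(result)
    else:
        logger.warning("year %d: only a %s network; QAP skipped",
                       year, next(iter(matrices)))
    return summary_rows, qap_info


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns a manifest of what was written.

    Any stage failure is reported with its stage name and the partially
    written output directory is removed.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "input"
    counters: dict[str, int] = {}
    try:
        if config.colony is not None:
            colony = config.colony
            if config.seed != colony.seed:
                colony = colony.with_seed(config.seed)
            events, truth = simulate_colony(colony)
            registry = antenna_registry_for(colony)
            window = config.window or colony.season
            events_frame(events).to_csv(outdir / "detections.csv", index=False)
            truth.write(outdir)
        else:
            registry = AntennaRegistry.read_csv(config.antennas_path)
            events = read_detections(
                config.detections_path, registry, strict=False, counters=counters
            )
            if config.window is None:
                raise ValueError("a study window is required for detection-log input")
            window = config.window
        n_read = len(events)

        stage = "windowing"
        events = filter_window(events, window)

        stage = "network construction"
        presence = daily_presence(events, registry, window)
        bins = bin_detections(events, registry, window)
        years = sorted(
            {_year_of(d) for d in presence["roost_day"]}
            | {_year_of(d) for d in bins["roost_day"]}
        )
        if not years:
            raise ValueError("no detections fall inside the study window")

        summary_rows: list[dict] = []
        qap_results: dict[int, dict] = {}
        for year in years:
            stage = f"year {year} analysis"
            p_y = presence[[_year_of(d) == year for d in presence["roost_day"]]]
            b_y = bins[[_year_of(d) == year for d in bins["roost_day"]]]
            rows, qap_info = _analyze_year(outdir / str(year), year, p_y, b_y, config)
            summary_rows.extend(rows)
            if qap_info:
                qap_results[year] = qap_info

        stage = "reporting"
        full = pd.DataFrame(summary_rows).rename(
            columns={"avg_degree_centrality": "avg_degree"}
        )
        full.to_csv(outdir / "summary_full.csv", index=False)
        rounded = full.copy()
        rounded["density"] = rounded["density"].round(2)
        rounded["centralization"] = rounded["centralization"].round(2)
        rounded["avg_degree"] = rounded["avg_degree"].round(1)
        rounded.to_csv(outdir / "summary.csv", index=False)

        manifest = {
            "version": __version__,
            "seed": config.seed,
            "alignment": config.alignment,
            "threshold": config.threshold,
            "n_permutations": config.n_permutations,
            "window": {
                "start": window.start_date.isoformat(),
                "end": window.end_date.isoformat(),
                "day_rollover_hour": window.day_rollover_hour,
            },
            "events_read": n_read,
            "rows_skipped": counters,
            "events_in_window": len(events),
            "years": years,
            "summary": summary_rows,
            "qap": qap_results,
        }
        with open(outdir / "run_log.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        return manifest
    except Exception as exc:
        shutil.rmtree(outdir, ignore_errors=True)
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc
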