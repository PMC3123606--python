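"""End-to-end analysis pipeline.

For one dataset: partition by the consensus structure, run saturation
tests on loops, stems and the combined data, fit all 14 analysis setups
(the DNA-only GTR setup plus 13 mixed RNA/DNA setups), fit the loop-only
and stem-only DNA analyses, compute Robinson-Foulds tables between the
combined-data trees and the partition-restricted trees, evaluate
benchmark clades, and render a report bundle.

Failure of one setup does not abort the others; errors are collected in
the report.  The whole run is deterministic under its master seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .likelihood import build_setup_partitions, tree_search
from .models import SETUP_NAMES
from .saturation import iss_test, saturation_report
from .structure import partition_alignment
from .treecmp import benchmark_matrix, rf_distance

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Single entry point for a pipeline run; embedded in every report."""

    setups: tuple = SETUP_NAMES
    outgroup: frozenset = frozenset()
    clades: tuple = ()
    seed: int = 0
    opt_tol: float = 1e-2
    opt_max_rounds: int = 5
    opt_bl_xatol: float = 1e-5
    max_nni_rounds: int = 10
    optimize_exchangeabilities: bool = True
    issc_reps: int = 240

    def as_dict(self) -> dict:
        return {"setups": list(self.setups),
                "outgroup": sorted(self.outgroup),
                "clades": [{"name": c.name, "taxa": sorted(c.taxa)}
                           for c in self.clades],
                "seed": self.seed, "opt_tol": self.opt_tol,
                "opt_max_rounds": self.opt_max_rounds,
                "opt_bl_xatol": self.opt_bl_xatol,
                "max_nni_rounds": self.max_nni_rounds,
                "optimize_exchangeabilities": self.optimize_exchangeabilities,
                "issc_reps": self.issc_reps}


@dataclass
class RunMatrix:
    """Results of one dataset run across all setups."""

    dataset: str
    config: PipelineConfig
    fits: dict = field(default_factory=dict)        # setup -> FitResult
    errors: dict = field(default_factory=dict)      # setup -> message
    saturation: dict = field(default_factory=dict)  # partition -> IssResult
    restricted: dict = field(default_factory=dict)  # loops/stems -> FitResult
    rf_loops: dict = field(default_factory=dict)    # setup -> ComparisonResult
    rf_stems: dict = field(default_factory=dict)
    benchmark: pd.DataFrame | None = None
    timings: dict = field(default_factory=dict)

    def to_json(self) -> str:
        def cmp_dict(c):
            return {"rf": c.rf, "rf_normalized": round(c.rf_normalized, 6),
                    "n_shared": c.n_shared}

        payload = {
            "dataset": self.dataset,
            "config": self.config.as_dict(),
            "fits": {s: f.summary() for s, f in self.fits.items()},
            "errors": dict(self.errors),
            "saturation": {p: r.row() for p, r in self.saturation.items()},
            "restricted": {p: f.summary() for p, f in self.restricted.items()},
            "rf_loops": {s: cmp_dict(c) for s, c in self.rf_loops.items()},
            "rf_stems": {s: cmp_dict(c) for s, c in self.rf_stems.items()},
            "benchmark": (None if self.benchmark is None
                          else self.benchmark.to_dict(orient="index")),
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def _fit_setup(aln, pdata, setup, config) -> object:
    parts = build_setup_partitions(aln, setup, partitioned=pdata)
    return tree_search(parts, aln.taxa, seed=config.seed,
                       tol=config.opt_tol, max_rounds=config.opt_max_rounds,
                       bl_xatol=config.opt_bl_xatol,
                       max_nni_rounds=config.max_nni_rounds,
                       exchangeabilities=config.optimize_exchangeabilities)


def partition_restricted_ml(aln, part: str, *, partitioned=None, config=None):
    """DNA GTR+Gamma fit on only the loop columns or only the stem columns
    (stems analysed as plain nucleotide sites here)."""
    from .likelihood import encode_loop_partition

    config = config or PipelineConfig()
    pdata = partitioned or partition_alignment(aln)
    if part == "loops":
        matrix = pdata.loop_matrix()
    elif part == "stems":
        matrix = pdata.stem_matrix()
    else:
        raise PipelineError(f"unknown partition {part!r} (loops|stems)")
    if matrix.shape[1] == 0:
        raise PipelineError(f"empty {part} partition")
    ep = encode_loop_partition(matrix, name=part)
    from .likelihood import empirical_frequencies
    ep.freqs = empirical_frequencies(ep)
    return tree_search([ep], aln.taxa, seed=config.seed, tol=config.opt_tol,
                       max_rounds=config.opt_max_rounds,
                       bl_xatol=config.opt_bl_xatol,
                       max_nni_rounds=config.max_nni_rounds,
                       exchangeabilities=config.optimize_exchangeabilities)


def run_pipeline(aln, config: PipelineConfig, dataset: str = "dataset") -> RunMatrix:
    """Execute every stage on one StructuredAlignment."""
    t0 = time.time()
    matrix = RunMatrix(dataset=dataset, config=config)
    pdata = partition_alignment(aln)
    # saturation: loops, stems (as nucleotide columns), combined
    slices = {"loops": pdata.loop_matrix(), "stems": pdata.stem_matrix(),
              "combined": pdata.combined_matrix()}
    for name, sl in slices.items():
        if sl.shape[1] == 0:
            matrix.errors[f"saturation:{name}"] = "empty partition"
            continue
        matrix.saturation[name] = iss_test(
            sl, partition=name, seed=config.seed, issc_reps=config.issc_reps)
    matrix.timings["saturation"] = round(time.time() - t0, 3)
    # 14 setups
    for setup in config.setups:
        ts = time.time()
        try:
            matrix.fits[setup] = _fit_setup(aln, pdata, setup, config)
        except Exception as exc:  # keep other setups running
            log.warning("setup %s failed: %s", setup, exc)
            matrix.errors[setup] = f"{type(exc).__name__}: {exc}"
        matrix.timings[setup] = round(time.time() - ts, 3)
    # partition-restricted DNA analyses
    for part in ("loops", "stems"):
        try:
            matrix.restricted[part] = partition_restricted_ml(
                aln, part, partitioned=pdata, config=config)
        except Exception as exc:
            matrix.errors[f"restricted:{part}"] = f"{type(exc).__name__}: {exc}"
    # RF tables
    for setup, fit in matrix.fits.items():
        for part, table in (("loops", matrix.rf_loops),
                            ("stems", matrix.rf_stems)):
            if part in matrix.restricted:
                table[setup] = rf_distance(fit.tree,
                                           matrix.restricted[part].tree)
    # benchmark clades
    if config.clades and config.outgroup and matrix.fits:
        matrix.benchmark = benchmark_matrix(matrix.fits, config.clades,
                                            config.outgroup)
    matrix.timings["total"] = round(time.time() - t0, 3)
    return matrix


# ---------------------------------------------------------------------------
# reporting

def rf_delta_grid(matrix: RunMatrix) -> pd.DataFrame:
    """Per mixed setup: did the RF distance to the loop-only / stem-only
    tree decrease, increase, or stay unchanged relative to the DNA setup?"""
    rows = []
    base_l = matrix.rf_loops.get("GTR")
    base_s = matrix.rf_stems.get("GTR")
    for setup in matrix.fits:
        if setup == "GTR":
            continue
        row = {"setup": setup}
        for part, table, base in (("loops", matrix.rf_loops, base_l),
                                  ("stems", matrix.rf_stems, base_s)):
            cur = table.get(setup)
            if cur is None or base is None:
                row[part] = "n/a"
            elif cur.rf < base.rf:
                row[part] = "decreased"
            elif cur.rf > base.rf:
                row[part] = "increased"
            else:
                row[part] = "unchanged"
        rows.append(row)
    return pd.DataFrame(rows).set_index("setup") if rows else pd.DataFrame()


def render_reports(matrix: RunMatrix, outdir) -> dict:
    """Write the report bundle (JSON + TSVs + human-readable summary);
    returns the file paths.  An empty matrix yields a valid empty report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["json"] = outdir / "run_matrix.json"
    paths["json"].write_text(matrix.to_json() + "\n")
    if matrix.saturation:
        paths["saturation"] = outdir / "saturation.tsv"
        paths["saturation"].write_text(
            saturation_report(matrix.saturation.values()))
    grid_rows = []
    for setup in matrix.config.setups:
        fit = matrix.fits.get(setup)
        cell = {"setup": setup}
        if fit is None:
            cell["status"] = "error"
            cell["benchmark"] = "n/a"
        else:
            cell["status"] = "ok"
            if matrix.benchmark is not None and setup in matrix.benchmark.index:
                cell["benchmark"] = ("pass" if matrix.benchmark.loc[setup, "all_pass"]
                                     else "fail")
            else:
                cell["benchmark"] = "n/a"
            cell["logL"] = round(fit.logL, 3)
            cell["AICc"] = None if fit.aicc is None else round(fit.aicc, 3)
        grid_rows.append(cell)
    grid = pd.DataFrame(grid_rows).set_index("setup")
    paths["grid"] = outdir / "setup_grid.tsv"
    grid.to_csv(paths["grid"], sep="\t")
    delta = rf_delta_grid(matrix)
    paths["rf_delta"] = outdir / "rf_delta.tsv"
    delta.to_csv(paths["rf_delta"], sep="\t")
    lines = [f"dataset: {matrix.dataset}",
             f"setups run: {len(matrix.fits)} ok, {len(matrix.errors)} errors"]
    for name, res in matrix.saturation.items():
        lines.append(f"saturation[{name}]: Iss={res.iss:.3f} "
                     f"Iss.c(asym)={res.issc_asym:.3f} -> {res.verdict}")
    paths["summary"] = outdir / "summary.txt"
    paths["summary"].write_text("\n".join(lines) + "\n")
    if not matrix.fits:
        log.warning("empty run matrix: report contains no fits")
    return {k: str(v) for k, v in paths.items()}
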