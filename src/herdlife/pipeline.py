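"""End-to-end evaluation pipeline: simulate -> QC -> fit -> reports.

Each stage reads and writes delimited-text artifacts in the run's output
directory and logs row counts, so a run is reproducible and resumable by
stage.  Rerunning with the same configuration and seed reproduces
identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import genpar, modsel, records as rec, select as sel
from .basis import legendre_T
from .pedigree import PedigreeTable, prune_pedigree
from .rrm import ChainConfig, ModelSpec, build_design, gibbs_fit
from .simulate import SimulationConfig, simulate_dataset

log = logging.getLogger("herdlife")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    outdir: str = "herdlife_run"
    records_path: str | None = None
    pedigree_path: str | None = None
    simulate: dict | None = None          # SimulationConfig overrides
    definitions: tuple = ("TL",)
    culling_group: str = "all_reasons"
    order: int = 2
    residual_structure: str = "heterogeneous_by_age"
    compare_residual_structures: bool = False
    chain_length: int = 20_000
    burn_in: int = 10_000
    thin: int = 10
    max_generations: int = 10
    age_at_selection: int = 4
    top_fractions: tuple = (0.01, 0.10)
    min_daughters: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.burn_in >= self.chain_length:
            raise ValueError("burn_in must be smaller than chain_length")
        if self.records_path is None and self.simulate is None:
            raise ValueError("either records_path or simulate must be given")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def stage_seed(self, label: str) -> np.random.SeedSequence:
        """Stable per-stage random stream (adding a stage never perturbs
        another stage's draws)."""
        import zlib

        return np.random.SeedSequence(
            [self.seed, zlib.crc32(label.encode()) % (2 ** 31)])


def _write(df: pd.DataFrame, path: Path, what: str) -> None:
    df.to_csv(path, index=False)
    log.info("%s: wrote %d rows to %s", what, len(df), path)


def stage_simulate(cfg: RunConfig, out: Path):
    sim_kwargs = dict(cfg.simulate or {})
    sim_kwargs.setdefault("seed", cfg.seed)
    scfg = SimulationConfig(**sim_kwargs)
    ped, tv, data = simulate_dataset(scfg)
    ped.write(out / "pedigree.csv")
    rec.write_records(data, out / "records.csv")
    log.info("simulate: %d animals, %d cow records (seed %d)",
             len(ped), len(data), scfg.seed)
    return out / "pedigree.csv", out / "records.csv"


def stage_prepare(cfg: RunConfig, out: Path, records_path, pedigree_path):
    parsed, errors = rec.read_records(records_path)
    kept, report = rec.apply_quality_control(parsed)
    report.parse_errors = errors
    _write(report.to_frame(), out / "qc_report.csv", "qc")
    panels = {}
    for d in cfg.definitions:
        panel = rec.build_longevity_panel(kept, d).subset_group(cfg.culling_group)
        panel.write(out / f"panel_{d}.csv")
        panels[d] = panel
        log.info("prepare: %s panel, %d cows x %d ages", d,
                 panel.n_cows, len(panel.ages))
    ped = PedigreeTable.read(pedigree_path)
    phen = sorted({c for p in panels.values() for c in p.cow_ids})
    ped = prune_pedigree(ped, phen, cfg.max_generations)
    ped.write(out / "pedigree_pruned.csv")
    summary = rec.summarize_life_histories(kept)
    _write(summary["by_group"], out / "descriptives.csv", "descriptives")
    return kept, panels, ped


def stage_fit(cfg: RunConfig, out: Path, kept, panels, ped,
              residual_structure=None):
    residual = residual_structure or cfg.residual_structure
    spec = ModelSpec(order=cfg.order, residual_structure=residual)
    fits = {}
    for d, panel in panels.items():
        chain = ChainConfig(length=cfg.chain_length, burn_in=cfg.burn_in,
                            thin=cfg.thin,
                            seed=int(cfg.stage_seed(f"fit_{d}_{residual}")
                                     .generate_state(1)[0] % (2 ** 31)))
        design = build_design(panel, kept, spec, ped=ped)
        draws = gibbs_fit(design, spec, chain)
        draws.save(out / f"draws_{d}_{residual}.npz")
        fits[d] = (design, draws, spec)
        log.info("fit %s (%s): %d obs, %d retained draws", d, residual,
                 design.n_obs, draws.n_retained)
    return fits


def stage_compare(cfg: RunConfig, out: Path, kept, panels, ped):
    rows = []
    fits_by_structure = {}
    for structure in ("homogeneous", "heterogeneous_by_age"):
        fits = stage_fit(cfg, out, kept, panels, ped,
                         residual_structure=structure)
        fits_by_structure[structure] = fits
    for d in panels:
        scores = [modsel.dic(fits_by_structure[s][d][1],
                             fits_by_structure[s][d][0], label=s)
                  for s in fits_by_structure]
        table = modsel.comparison_table(scores)
        table.insert(0, "definition", d)
        rows.append(table)
    table = pd.concat(rows, ignore_index=True)
    _write(table, out / "model_comparison.csv", "compare")
    return table, fits_by_structure


def stage_genpar(cfg: RunConfig, out: Path, fits):
    T = legendre_T(cfg.order)
    results = {}
    for d, (design, draws, spec) in fits.items():
        gp = genpar.posterior_genetic_parameters(draws, T)
        _write(gp.h2_frame(), out / f"heritability_{d}.csv", f"h2 {d}")
        corr = pd.DataFrame(gp.corr_mean, index=gp.ages, columns=gp.ages)
        corr.to_csv(out / f"genetic_correlations_{d}.csv")
        results[d] = gp
    return results


def stage_select(cfg: RunConfig, out: Path, kept, fits):
    T = legendre_T(cfg.order)
    metrics = sel.observed_daughter_metrics(kept)
    reports = {}
    for d, (design, draws, spec) in fits.items():
        ebv = sel.ebv_by_age(draws.a_mean, T)
        sires = pd.DataFrame({"sire_id": draws.a_ids})
        for age in range(2, 7):
            sires[f"ebv_{age}"] = ebv[:, age - 2]
        sires = sires.merge(metrics, on="sire_id", how="inner")
        if len(sires) >= 2:
            col = f"ebv_{cfg.age_at_selection}"
            sires["rbv"] = sel.rbv(sires[col].to_numpy())
        _write(sires, out / f"sire_report_{d}.csv", f"sires {d}")
        reports[d] = sires
    # commonly-selected proportions between definitions
    rows = []
    for frac in cfg.top_fractions:
        for d1 in reports:
            for d2 in reports:
                if d1 >= d2:
                    continue
                try:
                    s1 = sel.top_fraction(reports[d1], frac,
                                          cfg.min_daughters,
                                          cfg.age_at_selection)
                    s2 = sel.top_fraction(reports[d2], frac,
                                          cfg.min_daughters,
                                          cfg.age_at_selection)
                    n = min(len(s1), len(s2))
                    rows.append({"fraction": frac, "def_a": d1, "def_b": d2,
                                 "common_pct": sel.common_selected(s1[:n],
                                                                   s2[:n])})
                except ValueError as exc:
                    log.warning("select %s vs %s: %s", d1, d2, exc)
    if rows:
        _write(pd.DataFrame(rows), out / "commonly_selected.csv", "common")
    return reports


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute all stages; returns the output directory.

    Any stage failure aborts with the stage name and leaves a FAILED
    marker alongside the partial artifacts.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "run.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    log.setLevel(logging.INFO)
    stage = "init"
    try:
        records_path, pedigree_path = cfg.records_path, cfg.pedigree_path
        if cfg.simulate is not None:
            stage = "simulate"
            pedigree_path, records_path = stage_simulate(cfg, out)
        stage = "prepare"
        kept, panels, ped = stage_prepare(cfg, out, records_path,
                                          pedigree_path)
        if cfg.compare_residual_structures:
            stage = "compare"
            _, fits_by_structure = stage_compare(cfg, out, kept, panels, ped)
            fits = fits_by_structure[cfg.residual_structure]
        else:
            stage = "fit"
            fits = stage_fit(cfg, out, kept, panels, ped)
        stage = "genpar"
        stage_genpar(cfg, out, fits)
        stage = "select"
        stage_select(cfg, out, kept, fits)
        (out / "seed.txt").write_text(str(cfg.seed) + "\n")
    except Exception as exc:
        (out / "FAILED").write_text(f"stage {stage}: {exc}\n")
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc
    finally:
        log.removeHandler(fh)
        fh.close()
    return out
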