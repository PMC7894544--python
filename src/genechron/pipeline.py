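"""End-to-end orchestration: screen -> date -> reconcile -> summarize.

One declarative config drives either a fully synthetic run (every input
simulated with recorded seeds, ground truth retained) or a real-data run
(chronogram, gene trees, hit tables and calibrations read from files).  Every
stage logs its inputs and outputs into a manifest with SHA-256 checksums of
all tabular artifacts, so a rerun with the same config and seed reproduces
byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import chronology, screen as scr, synthetic, timing
from .reconcile import (PenaltyScheme, count_events, reconcile,
                        reconcile_bootstraps, slice_tree)
from .trees import DatedTree, GeneTree

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "make_fixtures"]


class PipelineError(RuntimeError):
    """Raised when a stage fails; the message names the stage and input."""


@dataclasses.dataclass
class SyntheticSettings:
    n_taxa: int = 20
    root_age: float = 3800.0
    birth_rate: float = 1.0e-3       # species births / lineage / Myr
    death_rate: float = 4.0e-4
    n_families: int = 5
    dup_rate: float = 5.0e-5         # gene events / lineage / Myr
    hgt_rate: float = 1.0e-4
    loss_rate: float = 5.0e-5
    n_nni: int = 0
    sites: int = 500
    n_hits: int = 60


@dataclasses.dataclass
class PipelineConfig:
    mode: str = "synthetic"                  # "synthetic" | "real"
    outdir: str = "genechron_out"
    seed: int = 0
    synthetic: SyntheticSettings = dataclasses.field(default_factory=SyntheticSettings)
    screen: scr.ScreenConfig = dataclasses.field(default_factory=scr.ScreenConfig)
    calibration: Optional[chronology.CalibrationSet] = None
    clock: chronology.ClockSettings = dataclasses.field(
        default_factory=lambda: chronology.ClockSettings(model="strict", cycles=600))
    penalties: PenaltyScheme = dataclasses.field(default_factory=PenaltyScheme)
    support_threshold: float = 0.5
    bin_width: float = 100.0
    allow_unconverged: bool = True           # short runs may fail ESS; log, not fail
    make_plots: bool = True
    # real-mode inputs
    chronogram_path: Optional[str] = None
    node_table_path: Optional[str] = None
    gene_tree_paths: dict[str, str] = dataclasses.field(default_factory=dict)
    hit_table_paths: dict[str, str] = dataclasses.field(default_factory=dict)
    alignment_path: Optional[str] = None
    calibration_path: Optional[str] = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for key in ("mode", "outdir", "seed", "support_threshold", "bin_width",
                    "allow_unconverged", "make_plots", "chronogram_path",
                    "node_table_path", "alignment_path", "calibration_path"):
            if key in raw:
                setattr(cfg, key, raw[key])
        if "synthetic" in raw:
            cfg.synthetic = SyntheticSettings(**raw["synthetic"])
        if "screen" in raw:
            cfg.screen = scr.ScreenConfig(**raw["screen"])
        if "clock" in raw:
            cfg.clock = chronology.ClockSettings(**raw["clock"])
        if "penalties" in raw:
            cfg.penalties = PenaltyScheme(**raw["penalties"])
        if "calibration" in raw:
            c = raw["calibration"]
            cfg.calibration = chronology.CalibrationSet(
                root_mean=c["root_mean"], root_sd=c.get("root_sd", 200.0),
                minima=[chronology.CladeMinimum(tuple(m["labels"]), m["min_age"])
                        for m in c.get("minima", [])])
        cfg.gene_tree_paths = dict(raw.get("gene_tree_paths", {}))
        cfg.hit_table_paths = dict(raw.get("hit_table_paths", {}))
        return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Manifest:
    def __init__(self, outdir: Path, config_echo: dict):
        self.outdir = outdir
        self.data = {"config": config_echo, "artifacts": {}, "notes": []}

    def add(self, name: str, path: Path, checksum: bool = True) -> None:
        entry = {"path": str(path.relative_to(self.outdir))}
        if checksum:
            entry["sha256"] = _sha256(path)
        self.data["artifacts"][name] = entry

    def note(self, text: str) -> None:
        self.data["notes"].append(text)

    def write(self) -> Path:
        path = self.outdir / "manifest.json"
        path.write_text(json.dumps(self.data, indent=2, sort_keys=True) + "\n")
        return path


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"[{name}] {exc}") from exc
        return wrapped
    return deco


def _default_calibration(tree: DatedTree, root_mean: float,
                         rng: np.random.Generator,
                         n_minima: int = 5) -> chronology.CalibrationSet:
    """Hard minima on random clades at half their true age (always satisfiable)."""
    internal = [n for n in tree.postorder() if not n.is_leaf and n.parent is not None]
    rng.shuffle(internal)
    minima = []
    for node in internal[:n_minima]:
        leaves = node.leaves()
        labels = (leaves[0].label, leaves[-1].label)
        if len(set(labels)) < 2:
            continue
        minima.append(chronology.CladeMinimum(labels, round(0.5 * node.age, 2)))
    return chronology.CalibrationSet(root_mean=root_mean, root_sd=200.0,
                                     minima=minima)


@_stage("inputs")
def _prepare_inputs(cfg: PipelineConfig, outdir: Path, manifest: _Manifest):
    """Simulate (synthetic mode) or load (real mode) every upstream input."""
    if cfg.mode == "synthetic":
        s = cfg.synthetic
        species = synthetic.simulate_dated_tree(
            s.n_taxa, s.birth_rate, s.death_rate, s.root_age, seed=cfg.seed)
        families: dict[str, GeneTree] = {}
        truth: dict[str, synthetic.TrueEventLog] = {}
        for i in range(s.n_families):
            name = f"fam{i:02d}"
            for attempt in range(50):
                params = synthetic.SimulationParams(
                    dup_rate=s.dup_rate, hgt_rate=s.hgt_rate, loss_rate=s.loss_rate,
                    seed=cfg.seed + 1000 * (i + 1) + attempt)
                gtree, log = synthetic.simulate_gene_family(species, params)
                if gtree is not None:
                    break
            else:
                raise PipelineError(f"[inputs] family {name} went extinct in 50 attempts")
            if s.n_nni > 0 and len(gtree.leaves) >= 4:
                gtree = synthetic.perturb_gene_tree(gtree, s.n_nni,
                                                    seed=cfg.seed + 77 + i)
            families[name], truth[name] = gtree, log
        alignment = synthetic.simulate_alignment(
            species, rate=cfg.clock.rate_median, sites=s.sites,
            alphabet_size=cfg.clock.alphabet_size, seed=cfg.seed + 7)
        cal = cfg.calibration or _default_calibration(
            species, s.root_age, np.random.default_rng(cfg.seed + 13))
        hit_tables = {
            name: synthetic.simulate_hit_table(
                s.n_hits, seed=cfg.seed + 500 + i, gene=name,
                evalue_ceiling=cfg.screen.ceiling_for(name),
                min_length_fraction=cfg.screen.min_length_fraction)
            for i, name in enumerate(families)
        }
        # persist the simulated inputs
        (outdir / "inputs").mkdir(exist_ok=True)
        sp_path = outdir / "inputs" / "species_tree.nwk"
        sp_path.write_text(species.to_newick() + "\n")
        manifest.add("species_tree", sp_path)
        aln_path = outdir / "inputs" / "species_alignment.fasta"
        alignment.to_fasta(aln_path)
        manifest.add("species_alignment", aln_path)
        cal_path = outdir / "inputs" / "calibrations.tsv"
        cal.to_file(cal_path)
        manifest.add("calibrations", cal_path)
        for name, gtree in families.items():
            p = outdir / "inputs" / f"{name}.nwk"
            p.write_text(gtree.to_newick() + "\n")
            manifest.add(f"gene_tree_{name}", p)
            t = outdir / "inputs" / f"{name}_truth.tsv"
            truth[name].to_tsv(t)
            manifest.add(f"truth_{name}", t)
        return species, families, truth, alignment, cal, hit_tables
    # real mode
    if not cfg.chronogram_path and not cfg.alignment_path:
        raise PipelineError("[inputs] real mode needs a chronogram or an alignment")
    species = None
    if cfg.chronogram_path:
        species = DatedTree.from_newick(Path(cfg.chronogram_path).read_text())
    families = {}
    for name, path in cfg.gene_tree_paths.items():
        p = Path(path)
        if not p.exists():
            raise PipelineError(f"[inputs] gene-tree file missing: {p}")
        # multi-tree files carry bootstrap replicates after the main tree
        families[name] = GeneTree.from_multi_newick(p.read_text())
    hit_tables = {}
    for name, path in cfg.hit_table_paths.items():
        p = Path(path)
        if not p.exists():
            raise PipelineError(f"[inputs] hit-table file missing: {p}")
        hit_tables[name] = pd.read_csv(p, sep="\t")
    alignment = (synthetic.Alignment.from_fasta(cfg.alignment_path)
                 if cfg.alignment_path else None)
    cal = (chronology.CalibrationSet.from_file(cfg.calibration_path)
           if cfg.calibration_path else cfg.calibration)
    return species, families, {}, alignment, cal, hit_tables


@_stage("screen")
def _run_screen(cfg: PipelineConfig, hit_tables, outdir: Path, manifest: _Manifest):
    (outdir / "screen").mkdir(exist_ok=True)
    log = scr.AttritionLog()
    retained = {}
    for name, table in sorted(hit_tables.items()):
        kept = scr.filter_hit_table(table, cfg.screen, gene=name, log=log)
        retained[name] = kept
        p = outdir / "screen" / f"{name}_retained.tsv"
        kept.to_csv(p, sep="\t", index=False)
        manifest.add(f"retained_{name}", p)
    p = outdir / "screen" / "attrition.tsv"
    log.to_frame().to_csv(p, sep="\t", index=False)
    manifest.add("attrition", p)
    return retained


@_stage("date")
def _run_date(cfg: PipelineConfig, species, alignment, cal, outdir: Path,
              manifest: _Manifest):
    if cal is None:
        raise PipelineError("[date] no calibration set available")
    traces = chronology.mcmc_date(species, alignment, cal, cfg.clock)
    diag = None
    if len(traces) >= 2:
        diag = chronology.convergence_diagnostics(traces[0], traces[1])
        if not diag.passed:
            manifest.note(
                f"convergence diagnostics failed (min ESS "
                f"{diag.ess.min():.1f}, maxdiff {diag.maxdiff:.3f})"
                + ("; summarizing anyway (allow_unconverged)"
                   if cfg.allow_unconverged else ""))
            if not cfg.allow_unconverged:
                raise PipelineError("[date] chains did not converge")
    chron, node_table = chronology.summarize_chronogram(
        traces, species, diagnostics=diag, override=cfg.allow_unconverged)
    (outdir / "date").mkdir(exist_ok=True)
    for c, trace in enumerate(traces):
        p = outdir / "date" / f"trace_chain{c}.tsv"
        trace.to_frame().to_csv(p, sep="\t", index=False, float_format="%.6f")
        manifest.add(f"trace_chain{c}", p)
    p = outdir / "date" / "chronogram.nwk"
    p.write_text(chron.to_newick() + "\n")
    manifest.add("chronogram", p)
    p = outdir / "date" / "node_ages.tsv"
    node_table.to_csv(p, sep="\t", float_format="%.6f")
    manifest.add("node_ages", p)
    return chron, node_table


@_stage("reconcile")
def _run_reconcile(cfg: PipelineConfig, chron: DatedTree, families,
                   outdir: Path, manifest: _Manifest):
    sliced = slice_tree(chron)
    results = {}
    frames = []
    for name, gtree in sorted(families.items()):
        if gtree.bootstraps:
            res = reconcile_bootstraps(
                gtree.bootstraps, sliced, cfg.penalties,
                support_threshold=cfg.support_threshold)
        else:
            res = reconcile(gtree, sliced, cfg.penalties)
        results[name] = res
        frames.append(res.events_frame(gene=name))
    (outdir / "reconcile").mkdir(exist_ok=True)
    events = (pd.concat(frames, ignore_index=True) if frames
              else pd.DataFrame(columns=["gene", "event_class", "donor", "recipient",
                                         "older_Mya", "younger_Mya", "midpoint_Mya",
                                         "support"]))
    p = outdir / "reconcile" / "events.tsv"
    events.to_csv(p, sep="\t", index=False, float_format="%.2f")
    manifest.add("events", p)
    counts = pd.DataFrame(
        {name: count_events(res) for name, res in sorted(results.items())}
    ).T
    counts.index.name = "gene"
    p = outdir / "reconcile" / "event_counts.tsv"
    counts.to_csv(p, sep="\t")
    manifest.add("event_counts", p)
    penalty = pd.DataFrame(
        [{"gene": n, "total_penalty": r.total_penalty}
         for n, r in sorted(results.items())])
    p = outdir / "reconcile" / "penalties.tsv"
    penalty.to_csv(p, sep="\t", index=False)
    manifest.add("penalties", p)
    mapping_rows = [
        {"gene": name, "gene_node": gnode, "segment": seg, "slice": sl}
        for name, res in sorted(results.items())
        for gnode, (seg, sl) in sorted(res.mapping.items())
    ]
    p = outdir / "reconcile" / "mapping.tsv"
    pd.DataFrame(mapping_rows,
                 columns=["gene", "gene_node", "segment", "slice"]
                 ).to_csv(p, sep="\t", index=False)
    manifest.add("mapping", p)
    return results, events


@_stage("summarize")
def _run_summarize(cfg: PipelineConfig, results, events, chron, node_table,
                   outdir: Path, manifest: _Manifest):
    (outdir / "summary").mkdir(exist_ok=True)
    notes: list[str] = []
    births = timing.birth_interval_table(results, chron, node_table,
                                         warn=notes.append)
    for n in notes:
        manifest.note(n)
    p = outdir / "summary" / "birth_intervals.tsv"
    births.to_csv(p, sep="\t", index=False)
    manifest.add("birth_intervals", p)
    density = timing.event_density(events, bin_width=cfg.bin_width)
    p = outdir / "summary" / "event_density.tsv"
    density.to_csv(p, sep="\t", index=False, float_format="%.6f")
    manifest.add("event_density", p)
    if cfg.make_plots and not density.empty:
        p = outdir / "summary" / "event_density.png"
        timing.plot_event_density(density, p)
        manifest.add("density_plot", p, checksum=False)
    return births, density


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage; returns the manifest dictionary (also written to
    ``<outdir>/manifest.json``)."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    echo = {"mode": cfg.mode, "seed": cfg.seed,
            "penalties": dataclasses.asdict(cfg.penalties),
            "support_threshold": cfg.support_threshold,
            "bin_width": cfg.bin_width}
    manifest = _Manifest(outdir, echo)
    species, families, truth, alignment, cal, hit_tables = _prepare_inputs(
        cfg, outdir, manifest)
    if hit_tables:
        _run_screen(cfg, hit_tables, outdir, manifest)
    if alignment is not None and species is not None:
        chron, node_table = _run_date(cfg, species, alignment, cal, outdir, manifest)
    elif species is not None:
        chron, node_table = species, None
        manifest.note("no alignment: using the input chronogram ages directly")
    else:
        raise PipelineError("[date] neither chronogram nor alignment available")
    results, events = _run_reconcile(cfg, chron, families, outdir, manifest)
    _run_summarize(cfg, results, events, chron, node_table, outdir, manifest)
    manifest.write()
    return manifest.data


def make_fixtures(seed: int, outdir) -> dict:
    """Write a small bundled test dataset: a 20-taxon chronogram, five gene
    families with planted event logs, hit tables, a six-row calibration file
    (root prior 3800 +/- 200 plus five clade minima), and an example
    key-residue spec (synthetic, illustrative only)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    species = synthetic.simulate_dated_tree(20, 1.0e-3, 4.0e-4, 3800.0, seed=seed)
    (out / "species_tree.nwk").write_text(species.to_newick() + "\n")
    cal = _default_calibration(species, 3800.0, np.random.default_rng(seed + 13))
    cal.to_file(out / "calibrations.tsv")
    paths = {"species_tree": str(out / "species_tree.nwk"),
             "calibrations": str(out / "calibrations.tsv")}
    for i in range(5):
        name = f"fam{i:02d}"
        for attempt in range(50):
            params = synthetic.SimulationParams(
                dup_rate=5e-5, hgt_rate=1e-4, loss_rate=5e-5,
                seed=seed + 1000 * (i + 1) + attempt)
            gtree, log = synthetic.simulate_gene_family(species, params)
            if gtree is not None:
                break
        (out / f"{name}.nwk").write_text(gtree.to_newick() + "\n")
        log.to_tsv(out / f"{name}_truth.tsv")
        hits = synthetic.simulate_hit_table(60, seed=seed + 500 + i, gene=name)
        hits.to_csv(out / f"{name}_hits.tsv", sep="\t", index=False)
        paths[name] = str(out / f"{name}.nwk")
    spec_path = out / "nifH_key_residues.synthetic.tsv"
    spec_path.write_text(
        "# gene:\tnifH\n"
        "# SYNTHETIC example residue spec for format illustration only --\n"
        "# not a curated nitrogenase residue set.\n"
        "10\tC\n25\tC\n40\tKR\n",
    )
    paths["residue_spec"] = str(spec_path)
    return paths
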