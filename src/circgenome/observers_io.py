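"""Config loading, time-series and snapshot writers, manifests, and the
command line.

All outputs are plain TSV (diff-able and language-neutral): a census time
series with one row per observation, a genome-length table, and per-step
spatial snapshots written as one matrix per channel.  A run manifest
(YAML) echoes the full configuration and seed so any output can be
replayed byte-for-byte.
"""

from __future__ import annotations

import argparse
import dataclasses
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .event_engine import SpeciesScope
from .model_core import Parameters, total_mass
from .species_classifier import (CATEGORY_NAMES, classify_categories,
                                 modal_genome_length)

logger = logging.getLogger("circgenome")

TIMESERIES_COLUMNS = ("step",) + CATEGORY_NAMES + tuple(
    c + "_free" for c in CATEGORY_NAMES)
TIMESERIES_SCHEMA = "census-tsv-v1"


# ---------------------------------------------------------------------------
# Snapshot
# ---------------------------------------------------------------------------

@dataclass
class Snapshot:
    """Per-room counts at one step: precursors plus one channel per census
    category.  Summing a channel over rooms reproduces the global census."""

    step: int
    N: int
    precursors: np.ndarray            # (N, N) int
    channels: dict                    # category -> (N, N) int array


def build_snapshot(state, params: Parameters) -> Snapshot:
    """Spatial per-room counts; accepts the object or the array state."""
    N = state.N
    channels = {c: np.zeros((N, N), dtype=np.int64) for c in CATEGORY_NAMES}

    def add(seq, circular, room):
        for cat in classify_categories(seq, circular, params):
            channels[cat][room // N, room % N] += 1

    if hasattr(state, "iter_strands"):
        for seq, circular, room, _engaged in state.iter_strands():
            add(seq, circular, room)
        return Snapshot(state.step_count, N,
                        state.prec.reshape(N, N).copy(), channels)
    for s in state.free_strands:
        add(s.seq, s.circular, s.room)
    for cx in state.complexes:
        add(cx.template.seq, cx.template.circular, cx.room)
        for seg in cx.segments:
            add(seg.seq, False, cx.room)
    return Snapshot(state.step, N,
                    state.precursors.reshape(N, N).copy(), channels)


def write_snapshot(snap: Snapshot, destination) -> Path:
    """Write a snapshot as stacked labelled matrices (TSV)."""
    path = Path(destination)
    lines = [f"# snapshot\tstep={snap.step}\tN={snap.N}"]
    for name, grid in [("precursors", snap.precursors),
                       *snap.channels.items()]:
        lines.append(f"# channel\t{name}")
        for row in np.asarray(grid):
            lines.append("\t".join(str(int(v)) for v in row))
    path.write_text("\n".join(lines) + "\n")
    return path


def read_snapshot(path) -> Snapshot:
    lines = Path(path).read_text().splitlines()
    head = dict(kv.split("=") for kv in lines[0].split("\t")[1:])
    step, N = int(head["step"]), int(head["N"])
    grids: dict[str, np.ndarray] = {}
    i = 1
    while i < len(lines):
        assert lines[i].startswith("# channel\t")
        name = lines[i].split("\t", 1)[1]
        rows = [[int(v) for v in lines[i + 1 + r].split("\t")]
                for r in range(N)]
        grids[name] = np.array(rows, dtype=np.int64)
        i += 1 + N
    prec = grids.pop("precursors")
    return Snapshot(step, N, prec, grids)


# ---------------------------------------------------------------------------
# Time series
# ---------------------------------------------------------------------------

def write_timeseries(censuses, destination) -> Path:
    """Census stream to TSV: a header row, one row per observation."""
    censuses = list(censuses)
    if not censuses:
        raise ValueError("empty census stream")
    path = Path(destination)
    with path.open("w") as fh:
        fh.write("\t".join(TIMESERIES_COLUMNS) + "\n")
        for c in censuses:
            row = [str(c.step)]
            row += [str(c.counts.get(k, 0)) for k in CATEGORY_NAMES]
            row += [str(c.free_counts.get(k, 0)) for k in CATEGORY_NAMES]
            fh.write("\t".join(row) + "\n")
    return path


def read_timeseries(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_genome_lengths(censuses, destination) -> Path:
    """Genome-length histograms as long-format TSV (step, length, count)."""
    path = Path(destination)
    with path.open("w") as fh:
        fh.write("step\tlength\tcount\n")
        for c in censuses:
            for length, count in c.genome_length_histogram.items():
                fh.write(f"{c.step}\t{length}\t{count}\n")
    return path


# ---------------------------------------------------------------------------
# Scenario-config (de)serialization
# ---------------------------------------------------------------------------

def _scope_to_dict(scope: SpeciesScope) -> dict:
    return {"topology": scope.topology,
            "contains_any": list(scope.contains_any),
            "not_contains": list(scope.not_contains)}


def _scope_from_dict(d: dict) -> SpeciesScope:
    return SpeciesScope(d.get("topology"),
                        tuple(d.get("contains_any", ())),
                        tuple(d.get("not_contains", ())))


def config_to_dict(cfg) -> dict:
    out = {
        "name": cfg.name,
        "parameters": cfg.parameters.to_dict(),
        "steps": cfg.steps,
        "seed": cfg.seed,
        "observe_every": cfg.observe_every,
        "snapshot_steps": list(cfg.snapshot_steps),
        "inoculations": [
            {"step": ev.step, "interval": ev.interval,
             "molecules": [list(m) for m in ev.molecules]}
            for ev in cfg.inoculations],
        "interventions": [
            {"step": iv.step, "parameter": iv.parameter, "value": iv.value,
             "scope": None if iv.scope is None else _scope_to_dict(iv.scope)}
            for iv in cfg.interventions],
        "stop_rule": None,
    }
    if cfg.stop_rule is not None:
        out["stop_rule"] = dataclasses.asdict(cfg.stop_rule)
    return out


def config_from_dict(d: dict):
    from .scenario_runner import (InoculationEvent, Intervention,
                                  ScenarioConfig, StopRule)
    stop = d.get("stop_rule")
    return ScenarioConfig(
        parameters=Parameters.from_dict(d.get("parameters", {})),
        steps=int(d.get("steps", 100_000)),
        seed=int(d.get("seed", 1)),
        inoculations=[
            InoculationEvent(int(ev["step"]),
                             [tuple(m) for m in ev["molecules"]],
                             int(ev.get("interval", 0)))
            for ev in d.get("inoculations", ())],
        interventions=[
            Intervention(int(iv["step"]), iv["parameter"], iv["value"],
                         None if iv.get("scope") is None
                         else _scope_from_dict(iv["scope"]))
            for iv in d.get("interventions", ())],
        stop_rule=None if stop is None else StopRule(**stop),
        observe_every=int(d.get("observe_every", 1000)),
        snapshot_steps=[int(s) for s in d.get("snapshot_steps", ())],
        name=d.get("name", "custom"))


def load_config(path):
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))


def save_config(cfg, path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(config_to_dict(cfg), sort_keys=False))
    return path


# ---------------------------------------------------------------------------
# Manifest
# ---------------------------------------------------------------------------

@dataclass
class RunManifest:
    """Everything needed to replay a run exactly."""

    config: dict
    seed: int
    version: str
    start_step: int
    end_step: int
    outputs: dict = field(default_factory=dict)
    schema: str = TIMESERIES_SCHEMA

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)

    def write(self, path) -> Path:
        path = Path(path)
        path.write_text(self.to_yaml())
        return path


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------

def _setup_logging(verbosity: int) -> None:
    level = logging.WARNING - 10 * verbosity
    logging.basicConfig(
        stream=sys.stderr, level=max(level, logging.DEBUG),
        format="%(asctime)s %(levelname)s %(name)s: %(message)s")


def _resolve_config(args):
    from .scenario_runner import preset
    if args.preset:
        cfg = preset(args.preset)
    elif args.config:
        cfg = load_config(args.config)
    else:
        raise ValueError("one of --preset or --config is required")
    if args.seed is not None:
        cfg.seed = args.seed
    if getattr(args, "steps", None):
        cfg.steps = args.steps
    if getattr(args, "observe_every", None):
        cfg.observe_every = args.observe_every
    if getattr(args, "snapshot_at", None):
        cfg.snapshot_steps = sorted(set(args.snapshot_at))
    return cfg


def _write_run_outputs(result, outdir: Path) -> dict:
    outdir.mkdir(parents=True, exist_ok=True)
    outputs = {}
    ts = write_timeseries(result.censuses, outdir / "timeseries.tsv")
    outputs["timeseries"] = ts.name
    gl = write_genome_lengths(result.censuses, outdir / "genome_lengths.tsv")
    outputs["genome_lengths"] = gl.name
    for snap in result.snapshots:
        p = write_snapshot(snap, outdir / f"snapshot_{snap.step}.tsv")
        outputs[f"snapshot_{snap.step}"] = p.name
    return outputs


def _cmd_run(args) -> int:
    from . import __version__
    from .scenario_runner import run
    cfg = _resolve_config(args)
    logger.info("running %s: N=%d T_NPB=%d steps=%d seed=%d", cfg.name,
                cfg.parameters.N, cfg.parameters.T_NPB, cfg.steps, cfg.seed)
    result = run(cfg, progress=args.progress)
    outdir = Path(args.out)
    outputs = _write_run_outputs(result, outdir)
    manifest = RunManifest(config=config_to_dict(cfg), seed=cfg.seed,
                           version=__version__, start_step=0,
                           end_step=result.state.step, outputs=outputs)
    manifest.write(outdir / "manifest.yaml")
    final = result.final_census
    logger.info("final census at step %d: mass=%d cir_rep=%d cir_repnr=%d",
                result.state.step, total_mass(result.state),
                final.counts["cir_rep"], final.counts["cir_repnr"])
    print(f"{cfg.name}: {result.state.step} steps -> {outdir}")
    return 0


def _cmd_presets(args) -> int:
    from .scenario_runner import PRESET_NAMES, preset
    for name in PRESET_NAMES:
        cfg = preset(name)
        p = cfg.parameters
        print(f"{name}\tN={p.N}\tT_NPB={p.T_NPB}\tsteps={cfg.steps}\t"
              f"inoculations={len(cfg.inoculations)}\t"
              f"interventions={len(cfg.interventions)}")
    return 0


def _parse_seeds(text: str) -> list[int]:
    if ".." in text:
        lo, hi = text.split("..")
        return list(range(int(lo), int(hi) + 1))
    return [int(s) for s in text.split(",")]


def _cmd_replicates(args) -> int:
    from . import __version__
    from .scenario_runner import run
    cfg0 = _resolve_config(args)
    seeds = _parse_seeds(args.seeds)
    outdir = Path(args.out)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for seed in seeds:
        cfg = dataclasses.replace(cfg0, seed=seed)
        result = run(cfg, progress=args.progress)
        final = result.final_census
        spread = final.counts["cir_rep"] + final.counts["cir_repnr"] \
            >= args.spread_threshold
        rows.append({
            "seed": seed,
            "final_cir_rep": final.counts["cir_rep"],
            "final_cir_repnr": final.counts["cir_repnr"],
            "final_cir_ct": final.counts["cir_ct"],
            "spread": int(spread),
            "modal_genome_length": modal_genome_length(final),
        })
        seed_dir = outdir / f"seed_{seed}"
        outputs = _write_run_outputs(result, seed_dir)
        RunManifest(config=config_to_dict(cfg), seed=seed,
                    version=__version__, start_step=0,
                    end_step=result.state.step,
                    outputs=outputs).write(seed_dir / "manifest.yaml")
    df = pd.DataFrame(rows)
    df.to_csv(outdir / "summary.tsv", sep="\t", index=False)
    frac = df["spread"].mean()
    modal = df["modal_genome_length"].mode()
    modal_val = int(modal.iloc[0]) if len(modal) else 0
    print(df.to_string(index=False))
    print(f"spread fraction: {frac:.2f}  modal final genome length: "
          f"{modal_val}")
    return 0


def _cmd_validate(args) -> int:
    from .model_core import validate_parameters
    cfg = _resolve_config(args)
    cfg.validate()
    warnings = validate_parameters(cfg.parameters)
    for w in warnings:
        print(f"warning: {w}")
    print(f"config {cfg.name!r} OK ({len(warnings)} warning(s))")
    return 0


def _build_parser() -> argparse.ArgumentParser:
    ap = argparse.ArgumentParser(
        prog="circgenome",
        description="Spatial Monte Carlo simulation of circular RNA "
                    "genomes and linear ribozymes on a toroidal grid.")
    ap.add_argument("-v", "--verbose", action="count", default=0)
    sub = ap.add_subparsers(dest="command", required=True)

    def common(sp, with_steps=True):
        sp.add_argument("--preset", help="named scenario preset")
        sp.add_argument("--config", help="scenario config file (YAML)")
        sp.add_argument("--seed", type=int, default=None)
        if with_steps:
            sp.add_argument("--steps", type=int, default=None)
            sp.add_argument("--observe-every", type=int, default=None,
                            dest="observe_every")

    sp = sub.add_parser("run", help="run one scenario")
    common(sp)
    sp.add_argument("--out", required=True, help="output directory")
    sp.add_argument("--snapshot-at", type=int, action="append",
                    dest="snapshot_at", default=None)
    sp.add_argument("--progress", action="store_true")
    sp.set_defaults(func=_cmd_run)

    sp = sub.add_parser("presets", help="list available presets")
    sp.set_defaults(func=_cmd_presets)

    sp = sub.add_parser("replicates", help="run several seeds and summarise")
    common(sp)
    sp.add_argument("--seeds", required=True,
                    help="e.g. 1..8 or 1,5,9")
    sp.add_argument("--out", required=True)
    sp.add_argument("--spread-threshold", type=int, default=20,
                    dest="spread_threshold")
    sp.add_argument("--progress", action="store_true")
    sp.set_defaults(func=_cmd_replicates)

    sp = sub.add_parser("validate", help="check a config without running")
    common(sp, with_steps=False)
    sp.set_defaults(func=_cmd_validate)
    return ap


def cli(argv=None) -> int:
    """Entry point; returns a process exit status."""
    parser = _build_parser()
    try:
        args = parser.parse_args(argv)
    except SystemExit as exc:
        return int(exc.code or 0)
    _setup_logging(args.verbose)
    try:
        return args.func(args)
    except (ValueError, FileNotFoundError) as exc:
        logger.error("%s", exc)
        return 2


def main() -> None:  # console-script entry
    raise SystemExit(cli())
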