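"""Reproducible simulate → correlate → diffusion-law / conformer runs.

One global seed is expanded deterministically into per-stage seeds, every
stage writes its tables (CSV/JSON/TIFF/PDB only), and a run report records
the config hash, software version, per-stage summaries and warnings, so a
rerun of the same config + seed reproduces every numeric output bitwise.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .acf import ACFModel
from .binning import bin_pixels
from .chains import ConformerSpec, generate_conformers, write_conformers_pdb
from .correlate import compute_acf_grid
from .difflaw import DiffusionLaw, aggregate_replicates, build_diffusion_law
from .imaging import OpticsCameraConfig, read_stack, render_stack, write_stack
from .ligands import closest_conformer, parse_ligands, rmsd_density, superpose_carbons
from .simulate import SimulationConfig, simulate_trajectories

__all__ = ["RunConfig", "RunReport", "run_pipeline", "make_report", "stage_seed"]

log = logging.getLogger("rafttrace")

SUBCOMMANDS = ("simulate", "imfcs", "difflaw", "conformers", "demo")


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed (< 2³¹) derived from the global seed."""
    return int(np.random.SeedSequence(
        [seed, zlib.crc32(stage.encode())]).generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """One CLI run: a subcommand, input/output paths, a seed, and the nested
    per-module parameter sections."""

    subcommand: str
    out_dir: Path
    seed: int = 0
    stack_paths: list[Path] = field(default_factory=list)
    pdb_paths: list[Path] = field(default_factory=list)
    reference: Optional[str] = None       # "file.pdb:CODE[:chain[:res_seq]]"
    ligand_code: str = "PLM"
    binnings: tuple[int, ...] = (1, 2, 3, 4, 5)
    n_bins: int = 20
    simulation: dict[str, Any] = field(default_factory=dict)
    optics: dict[str, Any] = field(default_factory=dict)
    conformer_spec: dict[str, Any] = field(default_factory=dict)
    triplet: bool = False
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.subcommand not in SUBCOMMANDS:
            raise ValueError(f"unknown subcommand {self.subcommand!r}")
        self.out_dir = Path(self.out_dir)
        self.stack_paths = [Path(p) for p in self.stack_paths]
        self.pdb_paths = [Path(p) for p in self.pdb_paths]

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload["out_dir"] = None  # location must not affect the numbers
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunReport:
    config_hash: str
    version: str
    seed: int
    stages: dict[str, dict[str, Any]]
    warnings: list[str]
    started: float
    finished: float

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=str)

    def write(self, path: Path) -> Path:
        path.write_text(self.to_json())
        return path


def make_report(artifacts: dict[str, dict[str, Any]], config_hash: str,
                seed: int, warnings: Optional[Sequence[str]] = None,
                started: Optional[float] = None) -> RunReport:
    """Assemble stage outputs into one report; every stage must agree on the
    config hash it was produced under."""
    if not artifacts:
        raise ValueError("no stage artifacts to report")
    for name, stage in artifacts.items():
        h = stage.get("config_hash", config_hash)
        if h != config_hash:
            raise ValueError(
                f"stage {name!r} carries config hash {h}, expected {config_hash}")
    now = time.time()
    return RunReport(config_hash=config_hash, version=__version__, seed=seed,
                     stages={k: {kk: vv for kk, vv in v.items() if kk != "config_hash"}
                             for k, v in artifacts.items()},
                     warnings=list(warnings or []),
                     started=started if started is not None else now,
                     finished=now)


def _parse_reference(spec: str) -> tuple[Path, str, Optional[str], Optional[int]]:
    parts = spec.split(":")
    if len(parts) < 2:
        raise ValueError(
            f"reference must be 'file.pdb:CODE[:chain[:res_seq]]', got {spec!r}")
    path, code = Path(parts[0]), parts[1]
    chain = parts[2] if len(parts) > 2 else None
    res_seq = int(parts[3]) if len(parts) > 3 else None
    return path, code, chain, res_seq


def _stage_simulate(config: RunConfig, out: Path) -> dict[str, Any]:
    sim_kwargs = dict(config.simulation)
    sim_kwargs.setdefault("seed", stage_seed(config.seed, "simulate"))
    opt_kwargs = dict(config.optics)
    opt_kwargs.setdefault("seed", stage_seed(config.seed, "camera"))
    if "roi" in opt_kwargs:
        opt_kwargs["roi"] = tuple(opt_kwargs["roi"])
    sim = SimulationConfig(**sim_kwargs)
    optics = OpticsCameraConfig(**opt_kwargs)
    log.info("simulating %s-mode trajectories (%d particles, %d steps)",
             sim.mode, sim.n_particles, sim.n_steps)
    traj = simulate_trajectories(sim)
    stack = render_stack(traj, optics)
    path = write_stack(stack, out / f"stack_{sim.mode}.tif")
    return {"stack": str(path), "mode": sim.mode,
            "mean_counts": float(stack.frames.mean()),
            "n_frames": stack.n_frames}


def _stage_imfcs(config: RunConfig, stack_path: Path, out: Path) -> dict[str, Any]:
    stack = read_stack(stack_path)
    rows = []
    for n_bin in config.binnings:
        series = bin_pixels(stack, n_bin)
        curves = compute_acf_grid(series.flat(), series.frame_time)
        acf_table = pd.concat([
            pd.DataFrame({"superpixel": i, "lag_s": c.lags, "G": c.G,
                          "var_G": c.var_G if c.var_G is not None else np.nan})
            for i, c in enumerate(curves)], ignore_index=True)
        acf_table.to_csv(out / f"acf_bin{n_bin}.csv", index=False)
        for i, curve in enumerate(curves):
            try:
                fit = ACFModel(curve, series.a_bin, series.omega0,
                               triplet=config.triplet).fit()
            except ValueError:
                continue
            rows.append({
                "n_bin": n_bin, "superpixel": i, "a_bin_um": series.a_bin,
                "A_eff_um2": fit.A_eff, "D": fit.params["D"], "N": fit.params["N"],
                "F_t": fit.params.get("F_t", 0.0), "t_f": fit.params.get("t_f", np.nan),
                "G_inf": fit.params["G_inf"], "tau_D_s": fit.tau_D,
                "chi2": fit.chi2_reduced, "converged": fit.converged})
    fits = pd.DataFrame(rows)
    fits.to_csv(out / "acf_fits.csv", index=False)
    conv = fits[fits.converged]
    return {"stack": str(stack_path), "n_fits": int(len(fits)),
            "n_converged": int(len(conv)),
            "median_D": float(conv.groupby("n_bin")["D"].median().median())
            if len(conv) else float("nan")}


def _stage_difflaw(config: RunConfig, stack_paths: Sequence[Path],
                   out: Path) -> dict[str, Any]:
    fits = []
    for path in stack_paths:
        stack = read_stack(path)
        points = build_diffusion_law(stack, config.binnings, triplet=config.triplet)
        result = DiffusionLaw(points).fit()
        fits.append(result)
        stem = path.stem.replace(".", "_")
        result.to_frame().to_csv(out / f"diffusion_law_{stem}.csv", index=False)
        (out / f"diffusion_law_{stem}.json").write_text(json.dumps({
            "tau_0_s": result.tau_0, "se_tau_0_s": result.se_tau_0,
            "D_eff_um2_s": result.D_eff, "r2": result.r2, "mode": result.mode,
            "flags": result.flags}, indent=2))
    summary = aggregate_replicates(
        fits, label="+".join(p.stem for p in stack_paths))
    pd.DataFrame([{
        "condition": summary.condition_label, "tau_0_mean_s": summary.tau_0_mean,
        "tau_0_sd_s": summary.tau_0_sd, "n": summary.n,
        "single_replicate": summary.single_replicate,
    }]).to_csv(out / "replicates.csv", index=False)
    last = fits[-1]
    return {"tau_0_s": last.tau_0, "D_eff": last.D_eff, "r2": last.r2,
            "mode": last.mode, "n_replicates": summary.n,
            "tau_0_mean_s": summary.tau_0_mean, "tau_0_sd_s": summary.tau_0_sd}


def _stage_conformers(config: RunConfig, out: Path) -> dict[str, Any]:
    if config.reference is None:
        raise ValueError("conformer analysis needs --reference file.pdb:CODE[...]")
    ref_path, ref_code, ref_chain, ref_seq = _parse_reference(config.reference)
    refs = parse_ligands(ref_path.read_text(), ref_code, source=ref_path.stem)
    if ref_chain is not None:
        refs = [r for r in refs if r.chain == ref_chain]
    if ref_seq is not None:
        refs = [r for r in refs if r.res_seq == ref_seq]
    if not refs:
        raise ValueError(f"no reference residue {ref_code} in {ref_path}")
    reference = refs[0]
    conformers = []
    for path in config.pdb_paths:
        conformers.extend(parse_ligands(path.read_text(), config.ligand_code,
                                        source=path.stem))
    if not conformers:
        raise ValueError(f"no {config.ligand_code} residues in the input files")
    rows = []
    for conf in conformers:
        sup = superpose_carbons(conf, reference)
        rows.append({"source_id": conf.source_id, "chain": conf.chain,
                     "res_seq": conf.res_seq, "n_matched": sup.n_matched,
                     "rmsd_A": sup.rmsd})
    pd.DataFrame(rows).to_csv(out / "rmsd_per_conformer.csv", index=False)
    density = rmsd_density(conformers, reference, n_bins=config.n_bins)
    pd.DataFrame({"bin_lo_A": density.bin_edges[:-1],
                  "bin_hi_A": density.bin_edges[1:],
                  "frequency": density.frequencies,
                  }).to_csv(out / "rmsd_density.csv", index=False)
    hit_id, hit_rmsd = closest_conformer(conformers, reference)
    (out / "closest.json").write_text(json.dumps(
        {"source_id": hit_id, "rmsd_A": hit_rmsd,
         "ligand_code": config.ligand_code}, indent=2))
    return {"n_conformers": density.dataset_size,
            "n_excluded": len(density.excluded),
            "occupied_bins": int(np.count_nonzero(density.frequencies)),
            "closest_source_id": hit_id, "closest_rmsd_A": hit_rmsd}


# Built-in demo: one free-diffusion measurement small enough to run in
# seconds yet long enough for a stable diffusion-law intercept.
DEMO_SIMULATION = dict(mode="free", D_out=1.0, box_side=8.64, n_particles=760,
                       n_steps=10_000)
DEMO_OPTICS = dict(roi=(12, 12), n_frames=10_000)
DEMO_BINNINGS = (1, 2, 3, 4)


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute one configured run and write its artifacts and report."""
    started = time.time()
    logging.basicConfig(level=config.log_level)
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, dict[str, Any]] = {}
    warnings: list[str] = []

    if config.subcommand == "demo":
        config = dataclasses.replace(
            config,
            simulation={**DEMO_SIMULATION, **config.simulation},
            optics={**DEMO_OPTICS, **config.optics},
            binnings=DEMO_BINNINGS)

    if config.subcommand in ("simulate", "demo"):
        artifacts["simulate"] = _stage_simulate(config, out)
    if config.subcommand == "imfcs":
        for path in config.stack_paths:
            if not path.exists():
                raise FileNotFoundError(f"stack not found: {path}")
            artifacts[f"imfcs:{path.stem}"] = _stage_imfcs(config, path, out)
        if not artifacts:
            raise ValueError("imfcs needs at least one --stack path")
    if config.subcommand in ("difflaw", "demo"):
        paths = list(config.stack_paths)
        if config.subcommand == "demo":
            paths = [Path(artifacts["simulate"]["stack"])]
        for path in paths:
            if not path.exists():
                raise FileNotFoundError(f"stack not found: {path}")
        if not paths:
            raise ValueError("difflaw needs at least one --stack path")
        artifacts["difflaw"] = _stage_difflaw(config, paths, out)
    if config.subcommand == "conformers":
        artifacts["conformers"] = _stage_conformers(config, out)

    report = make_report(artifacts, config.config_hash(), config.seed,
                         warnings, started)
    report.write(out / "report.json")
    return report
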