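"""End-to-end orchestration: build -> simulate -> analyze -> cluster ->
interface -> report, driven by a YAML config, with reproducible outputs.

Outputs are plain CSV/JSON. CSVs carry no timestamps so reruns with the
same config and seed are byte-identical; run metadata lives in the
provenance block (config hash, package version, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clustering as _clustering
from . import interface as _interface
from . import observables as obs
from . import synthetic
from .damage import DamageSite, make_ssb, set_flank_motif, swap_base, flip_base
from .geometry import shl_map
from .structure_io import (StructureModel, Trajectory, read_structure,
                           read_trajectory, write_structure, write_trajectory)

__all__ = ["RunConfig", "ReportBundle", "run_pipeline", "table1_report",
           "ConfigError"]

log = logging.getLogger("nucdamage.pipeline")


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    raw: dict
    outdir: Path
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw, base=Path(path).parent)

    @classmethod
    def from_dict(cls, raw: dict, base: Path | None = None) -> "RunConfig":
        base = base or Path.cwd()
        outdir = Path(raw.get("outdir", "nucdamage_out"))
        if not outdir.is_absolute():
            outdir = base / outdir
        cfg = cls(raw=raw, outdir=outdir, seed=int(raw.get("seed", 0)))
        cfg.validate(base)
        return cfg

    def validate(self, base: Path | None = None) -> None:
        base = base or Path.cwd()
        raw = self.raw
        if "synthetic" not in raw and "inputs" not in raw:
            raise ConfigError("config needs a 'synthetic' or 'inputs' block")
        if "inputs" in raw:
            for key in ("topology", "trajectory"):
                p = raw["inputs"].get(key)
                if p is None:
                    raise ConfigError(f"inputs.{key} missing")
                if not (base / p).exists() and not Path(p).exists():
                    raise ConfigError(f"inputs.{key}: no such file {p}")
        cl = raw.get("clustering") or {}
        if cl and float(cl.get("cutoff", 0.45)) <= 0:
            raise ConfigError("clustering.cutoff must be positive")

    @property
    def config_hash(self) -> str:
        # outdir is a location, not run content: identical analyses written
        # to different places hash (and reproduce) identically
        content = {k: v for k, v in self.raw.items() if k != "outdir"}
        blob = json.dumps(content, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()


@dataclass
class ReportBundle:
    outdir: Path
    series: pd.DataFrame
    files: dict[str, Path] = field(default_factory=dict)
    correlation: dict | None = None
    clustering: dict | None = None
    interface: dict | None = None
    provenance: dict = field(default_factory=dict)
    truth: pd.DataFrame | None = None


def _build_synthetic(cfg: RunConfig):
    syn = cfg.raw["synthetic"]
    helix = synthetic.HelixParams(**(syn.get("helix") or {}))
    seq = syn.get("sequence")
    if seq is None:
        n = int(syn.get("n_bp", 31))
        rng = np.random.default_rng(cfg.seed)
        seq = "".join(rng.choice(list("ACGT"), size=n))
    model = synthetic.build_bdna(seq, helix)
    shlmap = None
    if syn.get("superhelix") is not None:
        sh = synthetic.SuperhelixParams(**(syn.get("superhelix") or {}))
        model = synthetic.wrap_superhelix(model, sh)
        shlmap = shl_map(model, ("I", "J"), bp_per_turn=helix.bp_per_turn,
                         min_phosphates=min(100, 2 * len(seq) - 2))
    site = None
    dmg = syn.get("damage")
    if dmg:
        kind = dmg.get("kind", "ssb")
        key = (dmg.get("chain", "I"), int(dmg["resid"]))
        if kind == "ssb":
            model, site = make_ssb(model, key,
                                   five_cap=dmg.get("five_cap", "drp"))
            if dmg.get("motif", "default") == "default":
                model = set_flank_motif(model, site)
        elif kind in {"uracil-swap", "swap"}:
            model, site = swap_base(model, key, dmg.get("base", "U"))
        elif kind in {"flipped-base", "uracil-flip", "flip"}:
            model, _ = swap_base(model, key, dmg.get("base", "U"))
            model, site = flip_base(model, key, float(dmg.get("angle", 180.0)))
        else:
            raise ConfigError(f"unknown damage kind {kind!r}")
        if site is not None and shlmap is not None:
            site.shl = shlmap.shl_of.get(site.anchor)
    signals = []
    n_frames = int(syn.get("n_frames", 100))
    for s in syn.get("signals", []):
        sched = s.get("schedule")
        if sched is None:
            sched = np.linspace(float(s["start"]), float(s["stop"]), n_frames)
        signals.append(synthetic.DeformationSignal(
            target=s["target"], schedule=np.asarray(sched, float),
            noise_sigma=float(s.get("sigma", 0.0)), site=site,
            anchors=s.get("anchors", {}), seed=s.get("seed")))
    traj, truth = synthetic.make_trajectory(
        model, signals, n_frames=n_frames,
        dt_ps=float(syn.get("dt_ps", 10.0)), seed=cfg.seed, shlmap=shlmap,
        global_noise_sigma=float(syn.get("global_noise_sigma", 0.0)))
    return traj, site, shlmap, truth


def _load_inputs(cfg: RunConfig):
    inp = cfg.raw["inputs"]
    top = read_structure(inp["topology"])
    traj = read_trajectory(top, inp["trajectory"])
    site = None
    if inp.get("site"):
        site = DamageSite.from_json(inp["site"])
    shlmap = None
    if inp.get("dna_chains"):
        shlmap = shl_map(top, tuple(inp["dna_chains"]))
    return traj, site, shlmap, None


def run_pipeline(config: RunConfig | dict | str | Path) -> ReportBundle:
    """Run the configured analysis end to end; deterministic given seed."""
    if isinstance(config, (str, Path)):
        config = RunConfig.from_yaml(config)
    elif isinstance(config, dict):
        config = RunConfig.from_dict(config)
    cfg = config
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    bundle = ReportBundle(outdir=cfg.outdir, series=pd.DataFrame())

    if "synthetic" in cfg.raw:
        traj, site, shlmap, truth = _build_synthetic(cfg)
        bundle.truth = truth
        if truth is not None:
            p = cfg.outdir / "truth.csv"
            truth.to_csv(p, index=False)
            bundle.files["truth"] = p
        write_structure(traj.topology, cfg.outdir / "topology.pdb")
        write_trajectory(traj, cfg.outdir / "trajectory.pdb")
    else:
        traj, site, shlmap, _ = _load_inputs(cfg)

    wanted = cfg.raw.get("observables", ["dg", "phi"])
    rows = []
    series_by_name: dict[str, obs.ObservableSeries] = {}
    for name in wanted:
        try:
            s = _compute_series(name, traj, site, shlmap, cfg)
        except Exception as exc:   # partial failure: log and continue
            log.warning(json.dumps({"stage": "observable", "name": name,
                                    "error": str(exc)}))
            continue
        series_by_name[name] = s
        for t, v in zip(s.times, s.values):
            rows.append({"time_ps": t, "name": s.name, "value": v,
                         "units": s.units})
    bundle.series = pd.DataFrame(rows)
    p = cfg.outdir / "series.csv"
    bundle.series.to_csv(p, index=False, float_format="%.6f")
    bundle.files["series"] = p

    bins = int(cfg.raw.get("histogram_bins", 50))
    window = int(cfg.raw.get("window_frames", 10))
    hrows = []
    for name, s in series_by_name.items():
        st = obs.series_stats(s, window=window, bins=bins)
        edges, mass = st["histogram"]["edges"], st["histogram"]["mass"]
        for lo, hi, m in zip(edges[:-1], edges[1:], mass):
            hrows.append({"name": name, "bin_lo": lo, "bin_hi": hi, "mass": m})
    if hrows:
        p = cfg.outdir / "histograms.csv"
        pd.DataFrame(hrows).to_csv(p, index=False, float_format="%.6f")
        bundle.files["histograms"] = p

    if "dg" in series_by_name and "phi" in series_by_name:
        bundle.correlation = obs.correlate(series_by_name["dg"],
                                           series_by_name["phi"])
        p = cfg.outdir / "correlation.json"
        p.write_text(json.dumps(bundle.correlation, indent=2))
        bundle.files["correlation"] = p

    cl = cfg.raw.get("clustering")
    if cl:
        mat = _clustering.rmsd_matrix(traj, cl.get("selection"),
                                      stride=int(cl.get("stride", 1)))
        res = _clustering.gromos_cluster(mat, float(cl.get("cutoff", 0.45)))
        bundle.clustering = res.to_dict()
        p = cfg.outdir / "clusters.json"
        p.write_text(json.dumps(bundle.clustering, indent=2))
        bundle.files["clustering"] = p
        best = _clustering.best_cluster_frame(res, traj)
        write_structure(best, cfg.outdir / "best_cluster.pdb")

    icfg = cfg.raw.get("interface")
    if icfg:
        rep = table1_report(traj, icfg, window=window)
        bundle.interface = rep
        p = cfg.outdir / "interface.json"
        p.write_text(json.dumps(rep, indent=2))
        bundle.files["interface"] = p

    bundle.provenance = {
        "config_hash": cfg.config_hash,
        "seed": cfg.seed,
        "package": "nucdamage",
        "version": _version(),
        "n_frames": traj.n_frames,
    }
    p = cfg.outdir / "provenance.json"
    p.write_text(json.dumps(bundle.provenance, indent=2))
    bundle.files["provenance"] = p
    return bundle


def _version() -> str:
    from . import __version__
    return __version__


def _compute_series(name, traj, site, shlmap, cfg) -> obs.ObservableSeries:
    if name == "dg":
        return obs.gap_distance_series(traj, _require_site(site))
    if name == "phi":
        return obs.local_twist_series(traj, _require_site(site))
    if name == "dw":
        if shlmap is None:
            raise ConfigError("dw requires an SHL map (wrapped model)")
        return obs.gyre_gaping_series(traj, _require_site(site), shlmap)
    if name == "pairs" or name == "pair_distance":
        pcfg = cfg.raw.get("pair", {})
        return obs.pair_distance_series(traj, pcfg["a"], pcfg["b"],
                                        mode=pcfg.get("mode", "com"))
    raise ConfigError(f"unknown observable {name!r}")


def _require_site(site):
    if site is None:
        raise ConfigError("observable requires a damage site")
    return site


def table1_report(traj: Trajectory, icfg: dict, window: int = 10) -> dict:
    """Interface descriptors averaged over the trailing window of frames.

    Counts are averaged then rounded to the nearest integer; the area is a
    plain mean. The solvation free-energy column is imported or blank."""
    if window > traj.n_frames:
        raise ValueError(f"window {window} exceeds trajectory length "
                         f"{traj.n_frames}")
    frames = range(traj.n_frames - window, traj.n_frames)
    site = tuple(icfg["site"]) if icfg.get("site") else None
    acc: dict[str, list] = {k: [] for k in
                            ("area", "hb_t", "hb_s", "sb_t", "sb_s",
                             "hp_t", "hp_s")}
    for i in frames:
        model = traj.frame_model(i)
        rep = _interface.interface_report(
            model, icfg["a"], icfg["b"], site=site,
            label_a=icfg.get("label_a", "a"), label_b=icfg.get("label_b", "b"),
            n_sphere_points=int(icfg.get("n_sphere_points", 240)))
        acc["area"].append(rep.interface_area)
        acc["hb_t"].append(rep.hbonds_total)
        acc["hb_s"].append(rep.hbonds_site)
        acc["sb_t"].append(rep.salt_bridges_total)
        acc["sb_s"].append(rep.salt_bridges_site)
        acc["hp_t"].append(rep.hydrophobic_total)
        acc["hp_s"].append(rep.hydrophobic_site)
    out = {
        "partner_a": icfg.get("label_a", "a"),
        "partner_b": icfg.get("label_b", "b"),
        "window_frames": window,
        "interface_area_A2": float(np.mean(acc["area"])),
        "hbonds": [int(round(np.mean(acc["hb_t"]))),
                   int(round(np.mean(acc["hb_s"])))],
        "salt_bridges": [int(round(np.mean(acc["sb_t"]))),
                         int(round(np.mean(acc["sb_s"])))],
        "hydrophobic": [int(round(np.mean(acc["hp_t"]))),
                        int(round(np.mean(acc["hp_s"])))],
        "delta_gs_kcal_mol": icfg.get("delta_gs"),
    }
    # invariant: site counts never exceed totals
    for k in ("hbonds", "salt_bridges", "hydrophobic"):
        out[k][1] = min(out[k][1], out[k][0])
    return out
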